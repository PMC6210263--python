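name,cas,pc_twa,mac,stel,hazard_class,rfc,iur,provenance,rfc_canonical
Ammonia,7664-41-7,20,,30,III,0.5,,pc_twa:standard-canonical;rfc:study-calibrated,
Chlorine,7782-50-5,1,,,II,0.00015,,pc_twa:study-calibrated;rfc:study-calibrated,
Ozone,10028-15-6,0.3,,,III,0.4,,pc_twa:study-calibrated;rfc:study-calibrated,
Fluoride,16984-48-8,2,,,II,0.007,,pc_twa:standard-canonical;rfc:study-calibrated,
Sulfuric acid,7664-93-9,1,,2,II,0.003,,pc_twa:standard-canonical;rfc:study-calibrated,
Hydrogen chloride,7647-01-0,0.75,,,III,0.02,,pc_twa:study-calibrated;rfc:study-calibrated,
Ethylene glycol,107-21-1,20,,40,IV,0.4,,pc_twa:standard-canonical;rfc:study-calibrated,
Phosphine,7803-51-2,0.3,,,II,0.0003,,pc_twa:standard-canonical;rfc:study-calibrated,
Boron trifluoride,7637-07-2,3,,,II,0.013,,pc_twa:standard-canonical;rfc:study-calibrated,
Isopropanol,67-63-0,350,,700,IV,0.2,,pc_twa:standard-canonical;rfc:study-calibrated,
Benzene,71-43-2,6,,10,I,0.0726,0.0078,pc_twa:standard-canonical;rfc:study-calibrated;iur:standard-canonical,0.03
Toluene,108-88-3,50,,100,III,5.0,,pc_twa:standard-canonical;rfc:study-calibrated,
Xylene,1330-20-7,50,,100,III,0.1,,pc_twa:standard-canonical;rfc:study-calibrated,
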