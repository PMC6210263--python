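# Methods

## The two models

**EPA inhalation route.** Exposure is summarised per worker (or, in the
screening use here, per fixed post) by the exposure concentration

EC = Σᵢ CAᵢ · ETᵢ · EFᵢ · ED / AT   [mg/m³]

summing over the workplaces a worker rotates through: CA the airborne
concentration (mg/m³), ET the daily exposure time (h/day), EF the yearly
exposure frequency (day/year), ED the exposure duration (years). The
averaging time is AT = ED·24·365 h, so ED cancels and
EC = Σ CA·ET·EF/8760 — a pure clock-time dilution of the workplace
concentration. Non-cancer risk is screened by the hazard quotient
HQ = EC/RfC against the chronic inhalation reference concentration;
HQ ≥ 1 (boundary inclusive) is "higher" risk. Cancer risk is the linear
no-threshold bound Risk = IUR·EC; Risk > 10⁻⁶ (boundary exclusive) is
"higher". These are screening categories, not dose–response estimates.

An alternative lifetime-averaging mode (AT = 70·24·365 h with ED kept in
the numerator, so EC scales with ED/70) is available via
`Averaging.LIFETIME` for lifetime-averaged cancer estimates; the
exposure-period convention above is the default and is what the packaged
case study uses for both endpoints, keeping both HQ and Risk independent
of ED.

**Exposure-limit grading.** Each measurement is compared to the matching
Chinese occupational exposure limit — PC-TWA for time-weighted-average
measurements, MAC for ceiling, STEL for short-term; measurement records
carry the limit type explicitly. The exposure ratio B = measured/OEL is
mapped to a weight W_B, combined with the chemical's hazard-degree weight
W_D (ordinal class I extreme … IV mild) and the labor-intensity weight W_L
into the grading index G = W_D·W_B·W_L, banded Level 0 (G = 0) /
I (0 < G ≤ 6) / II (6 < G ≤ 24) / III (G > 24), with band edges closed on
the upper side. In the standard scheme W_B = 0 for all B ≤ 1: one zero
factor annihilates the product, so any plant testing below its limits is
Level 0 whatever W_D and W_L are. That annihilation is the entire
mechanism behind the method disagreement the package quantifies.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| ET | 10 | h/day | the case-study plant's daily exposure time |
| EF | 294 | day/year | calibrated so the case-study hazard quotients reproduce exactly; consistent with six-day weeks minus holidays. A config value, not a constant |
| ED | 1 (cancels) | years | irrelevant under exposure-period averaging |
| HQ threshold | 1 (≥) | — | screening definition |
| Risk threshold | 10⁻⁶ (>) | — | screening definition |
| W_D | I:8, II:4, III:2, IV:1 | — | package defaults consistent with the band maxima; override via YAML |
| W_B bands | ≤1:0, (1,3]:1, (3,6]:2, >6:3 | — | same |
| W_L | I:1, II:1.5, III:2, IV:2.5 | — | same |
| labor intensity | II | — | light-moderate electronics assembly; annihilated by W_B = 0 in the case study |
| fuzzy bandwidth | 0.1 | fraction of edge | see below |
| generator gm_ratio / gsd | 0.3 / 2.0 | — / — | a well-controlled plant testing below its limits — the regime where the methods disagree |

The governing weight tables for the grading method are standard-specific;
the packaged W_D/W_B/W_L values are package defaults chosen to be
consistent with the published band edges and the B ≤ 1 → 0 rule, and every
consumer accepts a user YAML (`wd`, `wb` breakpoint list, `wl`). The
case-study outcome (G = 0 for every agent) is independent of these tables,
and the tests assert that independence explicitly.

## Registry provenance

The registry stores, per agent, the Chinese limits, hazard class, RfC and
IUR, each numeric value carrying a provenance tag (`study-calibrated`,
`standard-canonical`, `user-supplied`) that the reporting layer echoes to
the log on every run. The packaged RfC values are the *study-calibrated*
set: back-calculated as EC/HQ from the case study's printed concentration
extremes and hazard quotients, so the shipped plant reproduces exactly.
Most coincide with canonical IRIS values (ammonia 0.5, phosphine 3×10⁻⁴,
hydrogen chloride 0.02, toluene 5, xylene 0.1 mg/m³). Benzene's
back-calculated 0.0726 mg/m³ matches no canonical source; the canonical
0.03 is recorded alongside it in the `rfc_canonical` column and the
study-calibrated value stays the default so the case study remains
internally consistent. Benzene's IUR is the canonical upper bound
7.8×10⁻³ (mg/m³)⁻¹; the case study's printed cancer risk for benzene is
not reconstructable from its stated inputs under any standard IUR and is
therefore exercised only as a classification example, never reproduced.

An internal-consistency audit test re-derives every RfC from the packaged
concentrations and the printed hazard quotients; the audit tolerance is
1% plus the half-ULP of the 2-decimal printed quotient (0.005/HQ), the
tightest bound those rounded values support.

## Invented extensions (clearly non-standard)

Two refinements address the grading method's bluntness below the limit;
neither has a standard functional form, so both are this package's own
constructions, off by default:

* **Refined exposure-ratio weight:** W_B = B on [0, 1) — the simplest rule
  that makes the weight depend monotonically on how close a below-limit
  exposure is to its limit — with the ordinary table lookup from B = 1 up.
  Refined mode never grades lower than standard mode for the same input.
* **Fuzzy banding:** each interior band edge e ∈ {6, 24} is softened over
  [e(1−bw), e(1+bw)]; within the zone the "above the edge" fraction rises
  linearly (0.5 exactly at the edge), and memberships are composed
  multiplicatively across the two edges so they are non-negative, sum to
  1 for every G, and collapse to the crisp bands as bw → 0. Softening is
  applied to G only, not to each input parameter — softening three factors
  of a product would require a joint membership model with no obvious
  canonical choice. G = 0 stays crisp (the Level 0 "band" is a point, and
  the edge at 0 has zero width).

## Synthetic plants

The generator draws one concentration per post × agent from a lognormal
with median gm_ratio × OEL and geometric standard deviation gsd — the
standard industrial-hygiene exposure model — truncating nothing (the
lognormal is already positive), attaching the configured schedule, and
deriving all randomness from a single integer seed (numpy `default_rng`).
It emulates the *structure* of a plant testing campaign: fixed posts, one
value per post × agent, a common schedule. It does not emulate temporal
autocorrelation, between-worker variance components, censoring at
detection limits, or mixture exposures — so passing tests show the
pipeline's arithmetic and bookkeeping are right under the assumed
lognormal regime, not that real plants behave this way.

The packaged case-study fixture uses the printed concentration *extremes*
as two pseudo-posts per agent (one where the range collapses), because the
underlying per-post values were never published; consequently the study's
per-agent high-risk percentages (76%/24%/9%) have no reproduction path,
and the ratio machinery is instead verified on constructed posts with
known category counts.

## Numerical choices

* Engines carry full double precision end to end; only report rendering
  rounds — HQ to 2 decimals (decimal half-up, matching how the reference
  values are printed), Risk to 2 significant figures in scientific
  notation.
* Threshold boundaries are exact: HQ = 1 is "higher", Risk = 10⁻⁶ is
  "lower", grading band upper bounds at 6 and 24 are inclusive. Tests pin
  these with `nextafter` probes.
* The exposure estimator is checked against a brute-force hour-grid
  oracle (accumulate CA over every exposed hour of a simulated year,
  divide by 8760) to 10⁻⁹ relative on 1,000 random integer-schedule
  profiles; ED-cancellation, homogeneity in CA, and additivity over stay
  sets are asserted as algebraic properties.
* Degenerate inputs are rejected, never coerced: empty stay lists, empty
  measurement files, non-positive limits/RfC, schedules outside
  (0, 24] × (0, 365], negative G, fuzzy bandwidth outside (0, 1).
* Agents lacking an RfC or IUR yield absent fields and a "not assessable"
  report line — never a fabricated zero; unknown agents abort a library
  batch call but are listed and skipped by the report runner so one typo
  does not void a campaign.
* Report regeneration is byte-identical under identical config and seed
  (sorted output, no timestamps).

## Problem sizes

The packaged case study is 24 measurements over 13 agents; property suites
use 1,000 random profiles for the exposure oracle, 500 posts for generator
median/GSD recovery, and 100–200 posts for the discordance regimes. The
full test suite runs in a few seconds on one CPU.

## Known limitations

* Single-agent screening only: no additive hazard index across mixtures,
  no dermal/oral routes, no aerosol size fractions, no pharmacokinetics.
* The grading weight tables are defaults, not the governing standard's
  text; any conclusion that depends on a non-zero W_B should supply the
  applicable tables.
* Provenance-tagged study-calibrated RfCs are calibration artifacts of the
  shipped case study; for de novo assessments supply canonical values
  (`rfc_canonical` is carried where it differs).
* The EF = 294 day/year default is a calibrated schedule, plausible but
  not documented by the source plant; sensitivity to EF is linear in EC
  and hence in both HQ and Risk.
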