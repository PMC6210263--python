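"""Chemical reference registry: occupational exposure limits and inhalation toxicity values.

Each registered agent carries the Chinese occupational exposure limits
(PC-TWA, MAC, STEL, mg/m³), an ordinal hazard-degree class, and the EPA
inhalation toxicity values — chronic reference concentration RfC (mg/m³)
and inhalation unit risk IUR ((mg/m³)⁻¹). Every numeric value carries a
provenance tag so a report can state where each constant came from:

``study-calibrated``
    value back-calculated so the packaged chip-plant case study is
    internally consistent (the study did not print its RfC/IUR inputs);
``standard-canonical``
    value taken from the canonical regulatory source (IRIS, GBZ 2.1);
``user-supplied``
    value provided by the caller.

Where a study-calibrated RfC differs from the canonical one, the optional
``rfc_canonical`` column records the canonical value alongside it.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import IO, Mapping

__all__ = [
    "HazardClass",
    "LimitType",
    "Verdict",
    "ChemicalAgent",
    "AgentRegistry",
    "RegistryError",
    "UnknownAgentError",
    "NoApplicableLimitError",
    "load_registry",
    "load_default_registry",
    "write_registry",
    "get_agent",
    "judge_against_oel",
]

#: Provenance tags accepted for registry values.
PROVENANCE_TAGS = frozenset({"study-calibrated", "standard-canonical", "user-supplied"})

REGISTRY_COLUMNS = [
    "name",
    "cas",
    "pc_twa",
    "mac",
    "stel",
    "hazard_class",
    "rfc",
    "iur",
    "provenance",
]
#: Extra columns the loader accepts beyond the required schema.
OPTIONAL_COLUMNS = ["rfc_canonical"]


class HazardClass(enum.Enum):
    """Ordinal hazard-degree class of a toxicant (GBZ 230 style): I extreme … IV mild."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class LimitType(enum.Enum):
    """Which occupational exposure limit a measurement is tested against."""

    TWA = "TWA"  # 8-h time-weighted average → PC-TWA
    MAC = "MAC"  # ceiling / peak → MAC
    STEL = "STEL"  # short-term → STEL


class Verdict(enum.Enum):
    QUALIFIED = "Qualified"
    NOT_QUALIFIED = "Not qualified"


class RegistryError(ValueError):
    """A registry file or row violates the schema or an invariant."""


class UnknownAgentError(KeyError):
    """Lookup of an agent absent from the registry (never silently defaulted)."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError repr-quotes; keep the message readable
        return f"unknown agent: {self.name!r}"


class NoApplicableLimitError(ValueError):
    """The agent has no exposure limit of the requested type."""


def normalize_name(name: str) -> str:
    """Casefold + trim; deliberately no synonym resolution."""
    return name.strip().casefold()


@dataclass(frozen=True)
class ChemicalAgent:
    """One registry entry; all concentrations in mg/m³, IUR in (mg/m³)⁻¹."""

    name: str
    cas: str | None = None
    pc_twa: float | None = None
    mac: float | None = None
    stel: float | None = None
    hazard_class: HazardClass | None = None
    rfc: float | None = None
    iur: float | None = None
    rfc_canonical: float | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise RegistryError("agent name must be non-empty")
        for attr in ("pc_twa", "mac", "stel", "rfc", "rfc_canonical"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise RegistryError(f"{self.name}: {attr} must be > 0, got {v}")
        if self.iur is not None and self.iur < 0:
            raise RegistryError(f"{self.name}: iur must be >= 0, got {self.iur}")
        for fieldname, tag in self.provenance.items():
            if tag not in PROVENANCE_TAGS:
                raise RegistryError(
                    f"{self.name}: provenance tag {tag!r} for {fieldname!r} not in "
                    f"{sorted(PROVENANCE_TAGS)}"
                )

    def limit(self, limit_type: LimitType) -> float | None:
        """The exposure limit matching a measurement's averaging type, if any."""
        return {
            LimitType.TWA: self.pc_twa,
            LimitType.MAC: self.mac,
            LimitType.STEL: self.stel,
        }[limit_type]

    @property
    def has_any_limit(self) -> bool:
        return any(v is not None for v in (self.pc_twa, self.mac, self.stel))


@dataclass(frozen=True)
class AgentRegistry:
    """Mapping of normalized agent name → :class:`ChemicalAgent`."""

    entries: Mapping[str, ChemicalAgent]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self.entries

    def get(self, name: str) -> ChemicalAgent:
        key = normalize_name(name)
        try:
            return self.entries[key]
        except KeyError:
            raise UnknownAgentError(name) from None

    def with_agent(self, agent: ChemicalAgent) -> "AgentRegistry":
        entries = dict(self.entries)
        entries[normalize_name(agent.name)] = agent
        return AgentRegistry(entries)


def _parse_float(raw: str, *, row: int, column: str) -> float | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        raise RegistryError(f"row {row}: column {column!r}: not a number: {raw!r}") from None


def _parse_provenance(raw: str, *, row: int) -> dict[str, str]:
    raw = raw.strip()
    if not raw:
        return {}
    out: dict[str, str] = {}
    for pair in raw.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        if ":" not in pair:
            raise RegistryError(
                f"row {row}: provenance entry {pair!r} must look like 'field:tag'"
            )
        fieldname, tag = (s.strip() for s in pair.split(":", 1))
        out[fieldname] = tag
    return out


def load_registry(source: str | Path | IO[str]) -> AgentRegistry:
    """Load a registry CSV (header ``name,cas,pc_twa,mac,stel,hazard_class,rfc,iur,provenance``).

    Empty cells mean "absent". Rows violating an invariant are rejected with
    a row-addressed :class:`RegistryError`; duplicate names (after
    normalization) are rejected.
    """
    if hasattr(source, "read"):
        return _load_registry_stream(source)  # type: ignore[arg-type]
    with open(source, newline="", encoding="utf-8") as fh:
        return _load_registry_stream(fh)


def _load_registry_stream(fh: IO[str]) -> AgentRegistry:
    reader = csv.DictReader(fh)
    header = reader.fieldnames
    if header is None:
        raise RegistryError("registry file is empty (no header)")
    missing = [c for c in REGISTRY_COLUMNS if c not in header]
    if missing:
        raise RegistryError(f"registry header missing required columns: {missing}")
    unknown = [c for c in header if c not in REGISTRY_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        raise RegistryError(f"registry header has unknown columns: {unknown}")

    entries: dict[str, ChemicalAgent] = {}
    for rownum, row in enumerate(reader, start=2):  # 1-based, after header
        name = (row["name"] or "").strip()
        if not name:
            raise RegistryError(f"row {rownum}: empty agent name")
        hc_raw = (row["hazard_class"] or "").strip()
        try:
            hazard_class = HazardClass(hc_raw) if hc_raw else None
        except ValueError:
            raise RegistryError(
                f"row {rownum}: hazard_class {hc_raw!r} not one of I/II/III/IV"
            ) from None
        try:
            agent = ChemicalAgent(
                name=name,
                cas=(row["cas"] or "").strip() or None,
                pc_twa=_parse_float(row["pc_twa"] or "", row=rownum, column="pc_twa"),
                mac=_parse_float(row["mac"] or "", row=rownum, column="mac"),
                stel=_parse_float(row["stel"] or "", row=rownum, column="stel"),
                hazard_class=hazard_class,
                rfc=_parse_float(row["rfc"] or "", row=rownum, column="rfc"),
                iur=_parse_float(row["iur"] or "", row=rownum, column="iur"),
                rfc_canonical=_parse_float(
                    row.get("rfc_canonical") or "", row=rownum, column="rfc_canonical"
                ),
                provenance=_parse_provenance(row["provenance"] or "", row=rownum),
            )
        except RegistryError as exc:
            raise RegistryError(f"row {rownum}: {exc}") from None
        key = normalize_name(name)
        if key in entries:
            raise RegistryError(f"row {rownum}: duplicate agent name {name!r}")
        entries[key] = agent
    return AgentRegistry(entries)


def write_registry(registry: AgentRegistry, dest: str | Path | IO[str]) -> None:
    """Write a registry back to CSV; numeric fields round-trip exactly (repr floats)."""
    if hasattr(dest, "write"):
        _write_registry_stream(registry, dest)  # type: ignore[arg-type]
        return
    with open(dest, "w", newline="", encoding="utf-8") as fh:
        _write_registry_stream(registry, fh)


def _write_registry_stream(registry: AgentRegistry, fh: IO[str]) -> None:
    cols = REGISTRY_COLUMNS + OPTIONAL_COLUMNS
    writer = csv.writer(fh)
    writer.writerow(cols)

    def fmt(v: float | None) -> str:
        return "" if v is None else repr(v)

    for agent in registry:
        writer.writerow(
            [
                agent.name,
                agent.cas or "",
                fmt(agent.pc_twa),
                fmt(agent.mac),
                fmt(agent.stel),
                agent.hazard_class.value if agent.hazard_class else "",
                fmt(agent.rfc),
                fmt(agent.iur),
                ";".join(f"{k}:{v}" for k, v in agent.provenance.items()),
                fmt(agent.rfc_canonical),
            ]
        )


def load_default_registry() -> AgentRegistry:
    """The packaged registry covering the chip-plant case-study agents."""
    text = resources.files("workrisk.data").joinpath("registry.csv").read_text("utf-8")
    return load_registry(io.StringIO(text))


def get_agent(registry: AgentRegistry, name: str) -> ChemicalAgent:
    """Name-normalized lookup; raises :class:`UnknownAgentError` if absent."""
    return registry.get(name)


def judge_against_oel(
    agent: ChemicalAgent,
    concentration: float,
    limit_type: LimitType = LimitType.TWA,
) -> Verdict:
    """Qualification verdict against the Chinese OEL matching the measurement type.

    Qualified iff concentration ≤ the applicable limit (boundary inclusive).
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    limit = agent.limit(limit_type)
    if limit is None:
        raise NoApplicableLimitError(
            f"{agent.name}: no {limit_type.value} limit available"
        )
    return Verdict.QUALIFIED if concentration <= limit else Verdict.NOT_QUALIFIED


def user_agent(name: str, **fields) -> ChemicalAgent:
    """Convenience constructor tagging every supplied numeric field user-supplied."""
    numeric = {k for k in ("pc_twa", "mac", "stel", "rfc", "iur") if fields.get(k) is not None}
    agent = ChemicalAgent(name=name, **fields)
    return replace(agent, provenance={k: "user-supplied" for k in numeric})
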