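"""Workplace occupational-hazards classification for toxic operations.

A toxic operation is banded by the grading index

    G = W_D × W_B × W_L

the product of three weights: hazard-degree of the chemical (W_D, from its
ordinal class I extreme … IV mild), occupational exposure ratio
(W_B, from B = measured concentration / applicable OEL), and the workers'
physical labor intensity (W_L, levels I–IV). G falls into four bands:

    G = 0        Level 0  relatively harmless operations
    0 < G ≤ 6    Level I  mildly hazardous operations
    6 < G ≤ 24   Level II moderately hazardous operations
    G > 24       Level III highly hazardous operations

In the standard scheme, W_B = 0 whenever B ≤ 1 — any workplace below its
exposure limit grades Level 0 regardless of the other weights. Two
refinements are offered as explicit, clearly non-standard modes: a
continuous W_B = B on [0, 1) ("refined" mode), and a fuzzy banding of G
that returns a membership degree per level instead of a crisp band.

The packaged default weight tables are consistent with the band maxima but
are package defaults, not regulatory text; override them via
:func:`WeightTables.from_yaml` when the governing tables are at hand.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import yaml

from .exposure import MeasurementRecord
from .registry import ChemicalAgent, HazardClass, NoApplicableLimitError

__all__ = [
    "GradingLevel",
    "LaborIntensity",
    "WeightMode",
    "WeightTables",
    "GradingResult",
    "DEFAULT_WEIGHT_TABLES",
    "exposure_ratio",
    "weight_for_exposure_ratio",
    "grading_index",
    "classify_grading",
    "grade_agent",
    "fuzzy_classify",
]

#: Band edges of the grading index (upper bounds, inclusive).
BAND_EDGES = (6.0, 24.0)


class GradingLevel(enum.Enum):
    LEVEL_0 = ("0", "relatively harmless operations")
    LEVEL_I = ("I", "mildly hazardous operations")
    LEVEL_II = ("II", "moderately hazardous operations")
    LEVEL_III = ("III", "highly hazardous operations")

    def __init__(self, rank: str, description: str):
        self.rank = rank
        self.description = description

    @property
    def label(self) -> str:
        return f"Level {self.rank} ({self.description})"

    def __lt__(self, other: "GradingLevel") -> bool:
        order = list(type(self))
        return order.index(self) < order.index(other)

    def __le__(self, other: "GradingLevel") -> bool:
        return self is other or self < other


class LaborIntensity(enum.Enum):
    """Physical-workload classification levels."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class WeightMode(enum.Enum):
    STANDARD = "standard"
    REFINED = "refined"


@dataclass(frozen=True)
class WeightTables:
    """The three weight tables feeding the grading index.

    ``wb_breakpoints`` is an ordered list of ``(upper_bound, weight)``
    pairs partitioning [0, ∞): B belongs to the first interval whose upper
    bound it does not exceed; the final pair has ``upper_bound = None``
    (open interval).
    """

    wd_by_class: Mapping[HazardClass, float]
    wb_breakpoints: Sequence[tuple[float | None, float]]
    wl_by_intensity: Mapping[LaborIntensity, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.wd_by_class.values()):
            raise ValueError("W_D weights must be >= 0")
        if any(w < 0 for w in self.wl_by_intensity.values()):
            raise ValueError("W_L weights must be >= 0")
        bps = list(self.wb_breakpoints)
        if not bps or bps[-1][0] is not None:
            raise ValueError("W_B breakpoints must end with an open interval (upper_bound null)")
        uppers = [u for u, _ in bps[:-1]]
        if any(u is None for u in uppers) or sorted(uppers) != uppers:
            raise ValueError("W_B upper bounds must be finite and increasing before the last")
        if any(w < 0 for _, w in bps):
            raise ValueError("W_B weights must be >= 0")

    def wd(self, hazard_class: HazardClass) -> float:
        return self.wd_by_class[hazard_class]

    def wl(self, intensity: LaborIntensity) -> float:
        return self.wl_by_intensity[intensity]

    def wb_lookup(self, b: float) -> float:
        for upper, weight in self.wb_breakpoints:
            if upper is None or b <= upper:
                return weight
        raise AssertionError("unreachable: final interval is open")

    @classmethod
    def from_yaml(cls, source: str | Path | IO[str]) -> "WeightTables":
        """Load weight tables from YAML with blocks ``wd``, ``wb``, ``wl``.

        ``wb`` is a list of ``{upper_bound, weight}`` mappings; the final
        entry's ``upper_bound`` is null for the open interval.
        """
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        try:
            wd = {HazardClass(k): float(v) for k, v in raw["wd"].items()}
            wb = [
                (None if e["upper_bound"] is None else float(e["upper_bound"]), float(e["weight"]))
                for e in raw["wb"]
            ]
            wl = {LaborIntensity(k): float(v) for k, v in raw["wl"].items()}
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed weight-table YAML: {exc}") from None
        return cls(wd_by_class=wd, wb_breakpoints=wb, wl_by_intensity=wl)

    def to_yaml(self, dest: str | Path | IO[str]) -> None:
        doc = {
            "wd": {k.value: v for k, v in self.wd_by_class.items()},
            "wb": [{"upper_bound": u, "weight": w} for u, w in self.wb_breakpoints],
            "wl": {k.value: v for k, v in self.wl_by_intensity.items()},
        }
        if hasattr(dest, "write"):
            yaml.safe_dump(doc, dest, sort_keys=False)
        else:
            with open(dest, "w", encoding="utf-8") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False)


DEFAULT_WEIGHT_TABLES = WeightTables(
    wd_by_class={
        HazardClass.I: 8.0,
        HazardClass.II: 4.0,
        HazardClass.III: 2.0,
        HazardClass.IV: 1.0,
    },
    wb_breakpoints=[(1.0, 0.0), (3.0, 1.0), (6.0, 2.0), (None, 3.0)],
    wl_by_intensity={
        LaborIntensity.I: 1.0,
        LaborIntensity.II: 1.5,
        LaborIntensity.III: 2.0,
        LaborIntensity.IV: 2.5,
    },
)


@dataclass(frozen=True)
class GradingResult:
    """Full audit trail of one grading: ratio, the three weights, G, and the band."""

    agent: str
    b: float
    wd: float
    wb: float
    wl: float
    g: float
    level: GradingLevel
    post_id: str | None = None


def exposure_ratio(measured: float, limit: float) -> float:
    """B = measured / limit, as a continuous ratio (weighting is a separate step)."""
    if not limit > 0:
        raise ValueError(f"limit must be > 0, got {limit}")
    if measured < 0:
        raise ValueError(f"measured must be >= 0, got {measured}")
    return measured / limit


def weight_for_exposure_ratio(
    b: float,
    tables: WeightTables = DEFAULT_WEIGHT_TABLES,
    mode: WeightMode = WeightMode.STANDARD,
) -> float:
    """Exposure-ratio weight W_B.

    Standard scheme: W_B = 0 for B ≤ 1 (below-limit workplaces carry no
    weight), table lookup above 1. Refined scheme: W_B = B on [0, 1) so a
    below-limit exposure still contributes in proportion to its size, table
    lookup from 1 up.
    """
    if b < 0:
        raise ValueError(f"b must be >= 0, got {b}")
    if mode is WeightMode.STANDARD:
        return 0.0 if b <= 1 else tables.wb_lookup(b)
    if mode is WeightMode.REFINED:
        return b if b < 1 else tables.wb_lookup(b)
    raise ValueError(f"unknown mode: {mode!r}")


def grading_index(wd: float, wb: float, wl: float) -> float:
    """G = W_D × W_B × W_L."""
    if wd < 0 or wb < 0 or wl < 0:
        raise ValueError("weights must be >= 0")
    return wd * wb * wl


def classify_grading(g: float) -> GradingLevel:
    """Band membership of the grading index; upper bounds at 6 and 24 are closed."""
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    if g == 0:
        return GradingLevel.LEVEL_0
    if g <= BAND_EDGES[0]:
        return GradingLevel.LEVEL_I
    if g <= BAND_EDGES[1]:
        return GradingLevel.LEVEL_II
    return GradingLevel.LEVEL_III


def grade_agent(
    measurement: MeasurementRecord,
    agent: ChemicalAgent,
    labor_intensity: LaborIntensity = LaborIntensity.II,
    tables: WeightTables = DEFAULT_WEIGHT_TABLES,
    mode: WeightMode = WeightMode.STANDARD,
) -> GradingResult:
    """Chain exposure ratio → weights → grading index → band, keeping intermediates."""
    limit = agent.limit(measurement.limit_type)
    if limit is None:
        raise NoApplicableLimitError(
            f"{agent.name}: no {measurement.limit_type.value} limit for grading"
        )
    if agent.hazard_class is None:
        raise ValueError(f"{agent.name}: hazard_class required for grading")
    b = exposure_ratio(measurement.ca, limit)
    wd = tables.wd(agent.hazard_class)
    wb = weight_for_exposure_ratio(b, tables, mode)
    wl = tables.wl(labor_intensity)
    g = grading_index(wd, wb, wl)
    return GradingResult(
        agent=agent.name, b=b, wd=wd, wb=wb, wl=wl, g=g,
        level=classify_grading(g), post_id=measurement.post_id,
    )


def fuzzy_classify(g: float, bandwidth: float = 0.1) -> dict[GradingLevel, float]:
    """Fuzzy band membership of the grading index.

    Each interior band edge e ∈ {6, 24} is softened over the zone
    [e·(1−bandwidth), e·(1+bandwidth)]: inside the zone the "above the
    edge" fraction rises linearly from 0 to 1, with 0.5 exactly at the
    edge. Memberships are composed so they are non-negative and sum to 1
    for every g, and the crisp bands are recovered as bandwidth → 0. The
    edge at 0 has zero width, so G = 0 stays crisply Level 0.
    """
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    if not 0 < bandwidth < 1:
        raise ValueError(f"bandwidth must be in (0, 1), got {bandwidth}")
    if g == 0:
        return {
            GradingLevel.LEVEL_0: 1.0,
            GradingLevel.LEVEL_I: 0.0,
            GradingLevel.LEVEL_II: 0.0,
            GradingLevel.LEVEL_III: 0.0,
        }

    def above(edge: float) -> float:
        lo, hi = edge * (1 - bandwidth), edge * (1 + bandwidth)
        if g <= lo:
            return 0.0
        if g >= hi:
            return 1.0
        return (g - lo) / (hi - lo)

    s6, s24 = above(BAND_EDGES[0]), above(BAND_EDGES[1])
    return {
        GradingLevel.LEVEL_0: 0.0,
        GradingLevel.LEVEL_I: 1.0 - s6,
        GradingLevel.LEVEL_II: s6 * (1.0 - s24),
        GradingLevel.LEVEL_III: s6 * s24,
    }
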