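"""Seedable synthetic plant scenarios, and the packaged chip-plant measurement set.

Workplace air concentrations are modelled as lognormal around a configured
fraction of each agent's exposure limit — the standard industrial-hygiene
exposure model: a geometric-mean ratio ``gm_ratio`` (median CA =
gm_ratio × OEL) and a geometric standard deviation ``gsd`` (multiplicative
spread; gsd = 1 is the degenerate point mass). Defaults (gm_ratio 0.3,
gsd 2.0) describe a well-controlled plant that tests comfortably below its
limits, which is exactly the regime where the two assessment methods can
disagree.

:func:`case_study_fixture` emits the chip-plant case study's measured
concentration extremes verbatim (two pseudo-posts per agent, one when the
printed range is a single value) with the study schedule ET = 10 h/day,
EF = 294 day/year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
import yaml

from .epa import Category, assess_post
from .exposure import DEFAULT_EF_DAYS, DEFAULT_ET_HOURS, MeasurementRecord
from .gbz import (
    DEFAULT_WEIGHT_TABLES,
    GradingLevel,
    LaborIntensity,
    WeightMode,
    WeightTables,
    grade_agent,
)
from .registry import AgentRegistry, LimitType

__all__ = [
    "AgentExposureSpec",
    "ScenarioConfig",
    "generate_scenario",
    "case_study_fixture",
    "discordance_experiment",
    "CASE_STUDY_RANGES",
]

# Chip-plant case study: (agent, min CA, max CA), mg/m³, all below their OELs.
CASE_STUDY_RANGES: tuple[tuple[str, float, float], ...] = (
    ("Ammonia", 0.500, 7.600),
    ("Chlorine", 0.030, 0.030),
    ("Ozone", 0.060, 0.170),
    ("Fluoride", 0.010, 0.036),
    ("Sulfuric acid", 0.013, 0.411),
    ("Hydrogen chloride", 0.011, 0.109),
    ("Ethylene glycol", 1.700, 1.700),
    ("Phosphine", 0.090, 0.143),
    ("Boron trifluoride", 1.213, 1.803),
    ("Isopropanol", 1.500, 1.500),
    ("Benzene", 1.200, 1.200),
    ("Toluene", 0.900, 0.900),
    ("Xylene", 1.600, 1.600),
)


@dataclass(frozen=True)
class AgentExposureSpec:
    """Lognormal exposure parameters for one agent, relative to its OEL."""

    name: str
    gm_ratio: float = 0.3  # median CA as a fraction of the OEL
    gsd: float = 2.0  # geometric standard deviation, >= 1

    def __post_init__(self) -> None:
        if not self.gm_ratio > 0:
            raise ValueError(f"{self.name}: gm_ratio must be > 0")
        if not self.gsd >= 1:
            raise ValueError(f"{self.name}: gsd must be >= 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """Synthetic plant description: posts × agents with a shared daily schedule."""

    n_posts: int
    agents: tuple[AgentExposureSpec, ...]
    et: float = DEFAULT_ET_HOURS
    ef: float = DEFAULT_EF_DAYS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "agents", tuple(self.agents))
        if self.n_posts < 1:
            raise ValueError(f"n_posts must be >= 1, got {self.n_posts}")
        if not self.agents:
            raise ValueError("scenario needs at least one agent")

    @classmethod
    def from_yaml(cls, source: str | Path | IO[str]) -> "ScenarioConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        agents = tuple(
            AgentExposureSpec(
                name=a["name"],
                gm_ratio=float(a.get("gm_ratio", 0.3)),
                gsd=float(a.get("gsd", 2.0)),
            )
            for a in raw["agents"]
        )
        return cls(
            n_posts=int(raw["n_posts"]),
            agents=agents,
            et=float(raw.get("et", DEFAULT_ET_HOURS)),
            ef=float(raw.get("ef", DEFAULT_EF_DAYS)),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, dest: str | Path | IO[str]) -> None:
        doc = {
            "n_posts": self.n_posts,
            "agents": [
                {"name": a.name, "gm_ratio": a.gm_ratio, "gsd": a.gsd} for a in self.agents
            ],
            "et": self.et,
            "ef": self.ef,
            "seed": self.seed,
        }
        if hasattr(dest, "write"):
            yaml.safe_dump(doc, dest, sort_keys=False)
        else:
            with open(dest, "w", encoding="utf-8") as fh:
                yaml.safe_dump(doc, fh, sort_keys=False)


def _slug(name: str) -> str:
    return name.strip().lower().replace(" ", "-")


def generate_scenario(
    config: ScenarioConfig, registry: AgentRegistry
) -> list[MeasurementRecord]:
    """Draw one measurement per post × agent; deterministic under ``config.seed``.

    CA is lognormal with median ``gm_ratio × OEL`` (the agent's PC-TWA) and
    multiplicative spread ``gsd``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[MeasurementRecord] = []
    for spec in config.agents:
        agent = registry.get(spec.name)  # raises UnknownAgentError
        if agent.pc_twa is None:
            raise ValueError(f"{agent.name}: scenario generation needs a PC-TWA limit")
        median = spec.gm_ratio * agent.pc_twa
        sigma = np.log(spec.gsd)
        cas = median * np.exp(sigma * rng.standard_normal(config.n_posts))
        for post, ca in enumerate(cas, start=1):
            records.append(
                MeasurementRecord(
                    post_id=f"post-{post:03d}",
                    agent=agent.name,
                    ca=float(ca),
                    limit_type=LimitType.TWA,
                    et=config.et,
                    ef=config.ef,
                )
            )
    return records


def case_study_fixture(
    et: float = DEFAULT_ET_HOURS, ef: float = DEFAULT_EF_DAYS
) -> list[MeasurementRecord]:
    """The chip-plant measurement extremes as pseudo-posts.

    Two records per agent (printed minimum and maximum concentration), one
    record where the printed range collapses to a single value; all tested
    as 8-h time-weighted averages.
    """
    records = []
    for name, cmin, cmax in CASE_STUDY_RANGES:
        slug = _slug(name)
        if cmin == cmax:
            points = [(f"{slug}-obs", cmin)]
        else:
            points = [(f"{slug}-min", cmin), (f"{slug}-max", cmax)]
        for post_id, ca in points:
            records.append(
                MeasurementRecord(
                    post_id=post_id, agent=name, ca=ca,
                    limit_type=LimitType.TWA, et=et, ef=ef,
                )
            )
    return records


def discordance_experiment(
    config: ScenarioConfig,
    registry: AgentRegistry,
    tables: WeightTables = DEFAULT_WEIGHT_TABLES,
    labor_intensity: LaborIntensity = LaborIntensity.II,
) -> pd.DataFrame:
    """Quantify method disagreement on a simulated plant.

    For each agent: the fraction of simulated posts graded Level 0
    (relatively harmless) by the exposure-limit method yet flagged higher
    non-cancer risk (HQ ≥ 1) by the hazard-quotient method. Agents must
    carry both an OEL and an RfC. Reproducible under ``config.seed``.
    """
    for spec in config.agents:
        agent = registry.get(spec.name)
        if agent.pc_twa is None or agent.rfc is None:
            raise ValueError(f"{agent.name}: discordance experiment needs both OEL and RfC")
    records = generate_scenario(config, registry)
    rows = []
    by_agent: dict[str, list[MeasurementRecord]] = {}
    for r in records:
        by_agent.setdefault(r.agent, []).append(r)
    for name, recs in by_agent.items():
        agent = registry.get(name)
        n_disc = 0
        for rec in recs:
            level = grade_agent(
                rec, agent, labor_intensity=labor_intensity,
                tables=tables, mode=WeightMode.STANDARD,
            ).level
            risk = assess_post(rec, registry)
            if level is GradingLevel.LEVEL_0 and risk.noncancer_category is Category.HIGHER:
                n_disc += 1
        rows.append(
            {
                "agent": name,
                "n_posts": len(recs),
                "discordant_fraction": n_disc / len(recs),
            }
        )
    return pd.DataFrame(rows, columns=["agent", "n_posts", "discordant_fraction"])
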