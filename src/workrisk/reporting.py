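"""Run orchestration and report rendering for the dual assessment.

``run_assessment`` drives both engines over one measurement file and
writes a small report bundle:

* ``results.csv`` — one row per post × agent with EC, HQ, cancer risk and
  the high/low categories;
* ``summary.csv`` — one row per agent mirroring a dual-method report
  (HQ range, high/low risk ratios, grading level);
* ``grading.csv`` — the classification audit trail (B, the three weights,
  G, level) per post × agent;
* ``report.txt`` — a human-readable rendering of the two tables plus the
  method-comparison table.

Rendering rounds (HQ to 2 decimals, risk to 2 significant figures); the
CSVs and engines carry full precision. Regeneration under the same config
and seed is byte-identical.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import epa, gbz
from .epa import AgentSummary, Category, RiskResult, format_hq, format_risk
from .exposure import (
    Averaging,
    MeasurementRecord,
    read_measurements,
    with_schedule,
)
from .gbz import (
    DEFAULT_WEIGHT_TABLES,
    GradingResult,
    LaborIntensity,
    WeightMode,
    WeightTables,
    fuzzy_classify,
)
from .registry import AgentRegistry, UnknownAgentError, load_default_registry, load_registry

__all__ = ["RunConfig", "ReportBundle", "run_assessment", "compare_methods"]

logger = logging.getLogger("workrisk")


@dataclass(frozen=True)
class RunConfig:
    """Everything one assessment run needs; paths resolve at run time."""

    measurements: str | Path
    registry: str | Path | None = None  # None → packaged registry
    weight_tables: str | Path | None = None  # None → package defaults
    out_dir: str | Path = "."
    et: float | None = None  # override measurement schedules when set
    ef: float | None = None
    mode: WeightMode = WeightMode.STANDARD
    labor_intensity: LaborIntensity = LaborIntensity.II
    fuzzy_bandwidth: float | None = None  # None → crisp banding only
    averaging: Averaging = Averaging.EXPOSURE_PERIOD
    seed: int = 0
    verbosity: int = 0


@dataclass(frozen=True)
class ReportBundle:
    results: list[RiskResult]
    summaries: list[AgentSummary]
    gradings: list[GradingResult]
    comparison: pd.DataFrame
    unresolved: list[str]  # agents not in the registry, listed not dropped
    paths: dict[str, Path] = field(default_factory=dict)


def _configure_logging(verbosity: int) -> None:
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    logging.basicConfig(stream=sys.stderr, level=level, format="%(levelname)s %(message)s")
    logger.setLevel(level)


def _echo_registry(registry: AgentRegistry) -> None:
    """Log every registry value with its provenance tag for auditability."""
    for agent in sorted(registry, key=lambda a: a.name):
        parts = []
        for fieldname in ("pc_twa", "mac", "stel", "rfc", "iur"):
            v = getattr(agent, fieldname)
            if v is not None:
                tag = agent.provenance.get(fieldname, "standard-canonical")
                parts.append(f"{fieldname}={v!r} [{tag}]")
        logger.info("registry %s: %s", agent.name, ", ".join(parts) or "no numeric values")


def run_assessment(config: RunConfig) -> ReportBundle:
    """Run both engines over a measurement file and write the report bundle.

    Unknown agents are reported as not assessable and listed in the text
    report; the run continues for the others. An empty measurement file is
    an error and produces no outputs.
    """
    _configure_logging(config.verbosity)
    registry = (
        load_default_registry() if config.registry is None else load_registry(config.registry)
    )
    _echo_registry(registry)
    tables = (
        DEFAULT_WEIGHT_TABLES
        if config.weight_tables is None
        else WeightTables.from_yaml(config.weight_tables)
    )
    records = read_measurements(config.measurements)
    if not records:
        raise ValueError(f"no measurement rows in {config.measurements}")
    records = with_schedule(records, et=config.et, ef=config.ef)

    resolved, unresolved = [], []
    for r in records:
        if r.agent in registry:
            resolved.append(r)
        else:
            unresolved.append(r.agent)
            logger.warning("agent %r not in registry: reported as not assessable", r.agent)
    unresolved = sorted(set(unresolved))
    if not resolved:
        raise ValueError("no measurement rows with a registry-resolvable agent")

    results, summaries = epa.assess_posts(resolved, registry, averaging=config.averaging)
    gradings = [
        gbz.grade_agent(
            rec,
            registry.get(rec.agent),
            labor_intensity=config.labor_intensity,
            tables=tables,
            mode=config.mode,
        )
        for rec in resolved
    ]
    comparison = compare_methods(results, gradings)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out_dir / "results.csv",
        "summary": out_dir / "summary.csv",
        "grading": out_dir / "grading.csv",
        "report": out_dir / "report.txt",
    }
    results_df(results).to_csv(paths["results"], index=False)
    summary_df(summaries, gradings).to_csv(paths["summary"], index=False)
    grading_df(gradings, config.fuzzy_bandwidth).to_csv(paths["grading"], index=False)
    paths["report"].write_text(
        render_text_report(results, summaries, gradings, comparison, unresolved, config),
        encoding="utf-8",
    )
    return ReportBundle(
        results=results,
        summaries=summaries,
        gradings=gradings,
        comparison=comparison,
        unresolved=unresolved,
        paths=paths,
    )


def results_df(results: Sequence[RiskResult]) -> pd.DataFrame:
    rows = [
        {
            "post_id": r.post_id,
            "agent": r.agent,
            "ec_mg_m3": r.ec,
            "hq": r.hq,
            "noncancer_category": r.noncancer_category.value if r.noncancer_category else "",
            "risk": r.risk,
            "cancer_category": r.cancer_category.value if r.cancer_category else "",
        }
        for r in sorted(results, key=lambda r: (r.agent, r.post_id))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "post_id", "agent", "ec_mg_m3", "hq",
            "noncancer_category", "risk", "cancer_category",
        ],
    )


def summary_df(
    summaries: Sequence[AgentSummary], gradings: Sequence[GradingResult]
) -> pd.DataFrame:
    level_by_agent: dict[str, str] = {}
    for g in gradings:
        # worst (highest) band across the agent's posts
        prev = level_by_agent.get(g.agent)
        if prev is None or _level_order(g.level.label) > _level_order(prev):
            level_by_agent[g.agent] = g.level.label
    rows = []
    for s in sorted(summaries, key=lambda s: s.agent):
        rows.append(
            {
                "agent": s.agent,
                "n_posts": s.n_posts,
                "hq_min": format_hq(s.hq_min) if s.hq_min is not None else "n/a",
                "hq_max": format_hq(s.hq_max) if s.hq_max is not None else "n/a",
                "high_risk_ratio": "" if s.high_risk_ratio is None else f"{s.high_risk_ratio:.0%}",
                "low_risk_ratio": "" if s.low_risk_ratio is None else f"{s.low_risk_ratio:.0%}",
                "gbz_level": level_by_agent.get(s.agent, ""),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "agent", "n_posts", "hq_min", "hq_max",
            "high_risk_ratio", "low_risk_ratio", "gbz_level",
        ],
    )


def _level_order(label: str) -> int:
    for i, lv in enumerate(gbz.GradingLevel):
        if lv.label == label:
            return i
    return -1


def grading_df(
    gradings: Sequence[GradingResult], fuzzy_bandwidth: float | None = None
) -> pd.DataFrame:
    rows = []
    for g in sorted(gradings, key=lambda g: (g.agent, g.post_id or "")):
        row = {
            "post_id": g.post_id or "",
            "agent": g.agent,
            "b": g.b,
            "wd": g.wd,
            "wb": g.wb,
            "wl": g.wl,
            "g": g.g,
            "level": g.level.label,
        }
        if fuzzy_bandwidth is not None:
            memberships = fuzzy_classify(g.g, fuzzy_bandwidth) if g.g >= 0 else {}
            for level, m in memberships.items():
                row[f"membership_{level.rank}"] = round(m, 6)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(
    risk_results: Sequence[RiskResult], grading_results: Sequence[GradingResult]
) -> pd.DataFrame:
    """Join the two methods on post × agent and flag discordant verdicts.

    A row is discordant when the grading method calls the operation
    relatively harmless (Level 0) while the hazard-quotient method flags
    higher non-cancer risk. Raises on key mismatch between the two sets.
    """
    risk_by_key = {(r.post_id, r.agent): r for r in risk_results}
    grade_by_key = {(g.post_id, g.agent): g for g in grading_results}
    if set(risk_by_key) != set(grade_by_key):
        only_risk = sorted(set(risk_by_key) - set(grade_by_key))
        only_grade = sorted(set(grade_by_key) - set(risk_by_key))
        raise ValueError(
            f"method result sets cover different post × agent keys: "
            f"only-risk={only_risk}, only-grading={only_grade}"
        )
    rows = []
    for key in sorted(risk_by_key):
        r, g = risk_by_key[key], grade_by_key[key]
        discordant = (
            g.level is gbz.GradingLevel.LEVEL_0
            and r.noncancer_category is Category.HIGHER
        )
        rows.append(
            {
                "post_id": key[0],
                "agent": key[1],
                "hq": r.hq,
                "noncancer_category": (
                    r.noncancer_category.value if r.noncancer_category else ""
                ),
                "gbz_level": g.level.label,
                "discordant": discordant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["post_id", "agent", "hq", "noncancer_category", "gbz_level", "discordant"],
    )


def render_text_report(
    results: Sequence[RiskResult],
    summaries: Sequence[AgentSummary],
    gradings: Sequence[GradingResult],
    comparison: pd.DataFrame,
    unresolved: Sequence[str],
    config: RunConfig,
) -> str:
    buf = io.StringIO()
    w = buf.write
    w("Dual occupational inhalation-risk assessment\n")
    w("=" * 44 + "\n\n")
    w(f"measurements: {config.measurements}\n")
    w(f"grading mode: {config.mode.value}; labor intensity: {config.labor_intensity.value}; ")
    w(f"averaging: {config.averaging.value}\n\n")

    w("Per-post results (HQ to 2 decimals, risk to 2 significant figures)\n")
    disp = results_df(results).copy()
    disp["hq"] = [format_hq(v) if pd.notna(v) else "n/a" for v in disp["hq"]]
    disp["risk"] = [
        format_risk(v) if pd.notna(v) else "n/a" for v in disp["risk"]
    ]
    disp["ec_mg_m3"] = [f"{v:.6g}" for v in disp["ec_mg_m3"]]
    w(disp.to_string(index=False))
    w("\n\nPer-agent summary\n")
    w(summary_df(summaries, gradings).to_string(index=False))
    w("\n\nMethod comparison (discordant = Level 0 yet HQ >= 1)\n")
    cdisp = comparison.copy()
    cdisp["hq"] = [format_hq(v) if pd.notna(v) else "n/a" for v in cdisp["hq"]]
    w(cdisp.to_string(index=False))
    w("\n")
    if unresolved:
        w("\nNot assessable (agent missing from registry):\n")
        for name in unresolved:
            w(f"  - {name}\n")
    n_disc = int(comparison["discordant"].sum()) if len(comparison) else 0
    w(
        f"\n{n_disc} of {len(comparison)} post x agent assessments are discordant "
        "between the two methods.\n"
    )
    return buf.getvalue()
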