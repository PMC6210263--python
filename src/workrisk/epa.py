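"""Health-risk step of the EPA inhalation model.

Non-cancer risk is screened with the hazard quotient HQ = EC / RfC; HQ ≥ 1
flags elevated non-carcinogenic risk. Cancer risk is the linear upper bound
Risk = IUR × EC; Risk > 10⁻⁶ flags elevated carcinogenic risk. Agents with
no RfC (or IUR) in the registry are reported as not assessable on that
endpoint — never as a fabricated zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .exposure import Averaging, MeasurementRecord, exposure_concentration, profile_from_record
from .registry import AgentRegistry

__all__ = [
    "HQ_THRESHOLD",
    "RISK_THRESHOLD",
    "Category",
    "RiskResult",
    "AgentSummary",
    "hazard_quotient",
    "classify_noncancer",
    "cancer_risk",
    "classify_cancer",
    "assess_posts",
    "format_hq",
    "format_risk",
]

HQ_THRESHOLD = 1.0  # HQ >= 1 → higher non-cancer risk (boundary inclusive)
RISK_THRESHOLD = 1e-6  # Risk > 1e-6 → higher cancer risk (boundary exclusive)


class Category(enum.Enum):
    HIGHER = "higher"
    LOWER = "lower"


@dataclass(frozen=True)
class RiskResult:
    """EPA assessment of one post × agent; ``None`` fields mean "no toxicity value"."""

    post_id: str
    agent: str
    ec: float
    hq: float | None = None
    risk: float | None = None
    noncancer_category: Category | None = None
    cancer_category: Category | None = None

    @property
    def assessable(self) -> bool:
        return self.hq is not None or self.risk is not None


@dataclass(frozen=True)
class AgentSummary:
    """Per-agent roll-up across posts, mirroring a risk-report row."""

    agent: str
    n_posts: int
    hq_min: float | None
    hq_max: float | None
    high_risk_ratio: float | None
    low_risk_ratio: float | None

    @property
    def hq_range(self) -> tuple[float, float] | None:
        if self.hq_min is None or self.hq_max is None:
            return None
        return (self.hq_min, self.hq_max)


def hazard_quotient(ec: float, rfc: float) -> float:
    """HQ = EC / RfC (dimensionless)."""
    if rfc is None or not rfc > 0:
        raise ValueError(f"rfc must be > 0, got {rfc}")
    if ec < 0:
        raise ValueError(f"ec must be >= 0, got {ec}")
    return ec / rfc


def classify_noncancer(hq: float) -> Category:
    """Higher non-cancer risk iff HQ ≥ 1."""
    if hq < 0:
        raise ValueError(f"hq must be >= 0, got {hq}")
    return Category.HIGHER if hq >= HQ_THRESHOLD else Category.LOWER


def cancer_risk(ec: float, iur: float) -> float:
    """Risk = IUR × EC (lifetime excess cancer probability, upper bound)."""
    if iur is None or iur < 0:
        raise ValueError(f"iur must be >= 0, got {iur}")
    if ec < 0:
        raise ValueError(f"ec must be >= 0, got {ec}")
    return iur * ec


def classify_cancer(risk: float) -> Category:
    """Higher cancer risk iff Risk > 10⁻⁶ (strictly; 10⁻⁶ itself is lower)."""
    if risk < 0:
        raise ValueError(f"risk must be >= 0, got {risk}")
    return Category.HIGHER if risk > RISK_THRESHOLD else Category.LOWER


def assess_post(record: MeasurementRecord, registry: AgentRegistry,
                averaging: Averaging = Averaging.EXPOSURE_PERIOD,
                ed: float = 1.0) -> RiskResult:
    """Assess a single post × agent measurement (single-stay profile)."""
    agent = registry.get(record.agent)
    ec = exposure_concentration(profile_from_record(record, ed=ed), averaging=averaging)
    hq = risk = nc = cc = None
    if agent.rfc is not None:
        hq = hazard_quotient(ec, agent.rfc)
        nc = classify_noncancer(hq)
    if agent.iur is not None:
        risk = cancer_risk(ec, agent.iur)
        cc = classify_cancer(risk)
    return RiskResult(
        post_id=record.post_id,
        agent=agent.name,
        ec=ec,
        hq=hq,
        risk=risk,
        noncancer_category=nc,
        cancer_category=cc,
    )


def assess_posts(
    measurements: Sequence[MeasurementRecord],
    registry: AgentRegistry,
    averaging: Averaging = Averaging.EXPOSURE_PERIOD,
    ed: float = 1.0,
) -> tuple[list[RiskResult], list[AgentSummary]]:
    """Per-post EPA assessment plus per-agent summaries.

    Raises :class:`~workrisk.registry.UnknownAgentError` on the first
    unresolvable agent and :class:`ValueError` on empty input; callers that
    want partial-failure semantics filter first (see
    :func:`workrisk.reporting.run_assessment`).
    """
    if not measurements:
        raise ValueError("no measurements to assess")
    results = [assess_post(m, registry, averaging=averaging, ed=ed) for m in measurements]
    return results, summarize_by_agent(results)


def summarize_by_agent(results: Iterable[RiskResult]) -> list[AgentSummary]:
    by_agent: dict[str, list[RiskResult]] = {}
    for r in results:
        by_agent.setdefault(r.agent, []).append(r)
    summaries = []
    for agent, rs in by_agent.items():
        hqs = [r.hq for r in rs if r.hq is not None]
        if hqs:
            n_high = sum(1 for r in rs if r.noncancer_category is Category.HIGHER)
            n_assessed = len(hqs)
            summaries.append(
                AgentSummary(
                    agent=agent,
                    n_posts=len(rs),
                    hq_min=min(hqs),
                    hq_max=max(hqs),
                    high_risk_ratio=n_high / n_assessed,
                    low_risk_ratio=(n_assessed - n_high) / n_assessed,
                )
            )
        else:  # no RfC anywhere: not assessable, never fabricated zeros
            summaries.append(
                AgentSummary(
                    agent=agent, n_posts=len(rs),
                    hq_min=None, hq_max=None,
                    high_risk_ratio=None, low_risk_ratio=None,
                )
            )
    return summaries


def format_hq(hq: float | None) -> str:
    """Report rendering of a hazard quotient: 2 decimals, half-up."""
    if hq is None:
        return "n/a"
    return str(Decimal(repr(hq)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_risk(risk: float | None) -> str:
    """Report rendering of a cancer risk: scientific notation, 2 significant figures."""
    if risk is None:
        return "n/a"
    if risk == 0:
        return "0"
    return f"{risk:.1e}"
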