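"""Cost-effectiveness statistics for two-arm comparisons.

Computes cost-effectiveness ratios (CER), incremental cost and effect, the
incremental cost-effectiveness ratio (ICER), a dominance classification,
and a willingness-to-pay (WTP) decision.  Because a negative ICER is
ambiguous on its own (it arises both when an arm dominates and when it is
dominated), decisions always route through net monetary benefit:
``NMB = wtp * qaly - cost``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort_engine import ArmResult
from .errors import DomainError

logger = logging.getLogger(__name__)

A_DOMINANT = "a_dominant"
B_DOMINANT = "b_dominant"
TRADE_OFF = "trade_off"


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay threshold, conventionally a GDP-per-capita multiple."""

    gdp_per_capita: float
    multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise DomainError(f"gdp_per_capita must be > 0, got {self.gdp_per_capita}")
        if self.multiplier <= 0:
            raise DomainError(f"multiplier must be > 0, got {self.multiplier}")

    @property
    def threshold(self) -> float:
        return self.gdp_per_capita * self.multiplier


def wtp_threshold(gdp_per_capita: float, multiplier: float = 3.0) -> WTPThreshold:
    """Build a WTP threshold of ``gdp_per_capita * multiplier``."""
    return WTPThreshold(gdp_per_capita, multiplier)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """``wtp * qaly - cost`` (RMB)."""
    if wtp < 0:
        raise DomainError(f"wtp must be >= 0, got {wtp}")
    return wtp * qaly - cost


def _classify_dominance(delta_cost: float, delta_qaly: float) -> str:
    a_better_cost, a_better_qaly = delta_cost < 0, delta_qaly > 0
    b_better_cost, b_better_qaly = delta_cost > 0, delta_qaly < 0
    if (a_better_cost or a_better_qaly) and not (b_better_cost or b_better_qaly):
        return A_DOMINANT
    if (b_better_cost or b_better_qaly) and not (a_better_cost or a_better_qaly):
        return B_DOMINANT
    return TRADE_OFF


@dataclass(frozen=True)
class CEAComparison:
    """Full two-arm comparison: arm a vs. comparator arm b."""

    label_a: str
    label_b: str
    cost_a: float
    cost_b: float
    qaly_a: float
    qaly_b: float
    delta_cost: float
    delta_qaly: float
    cer_a: float
    cer_b: float
    icer: float | None
    dominance: str
    wtp: float
    cost_effective: bool

    def to_rows(self) -> list[dict]:
        """Two result-table rows (arm a first), mirroring the standard layout."""
        return [
            {
                "Strategy": self.label_a,
                "Cost (RMB)": self.cost_a,
                "Incremental costs": self.delta_cost,
                "Effectiveness (QALYs)": self.qaly_a,
                "Incremental effectiveness": self.delta_qaly,
                "CER": self.cer_a,
                "ICER": self.icer,
            },
            {
                "Strategy": self.label_b,
                "Cost (RMB)": self.cost_b,
                "Incremental costs": None,
                "Effectiveness (QALYs)": self.qaly_b,
                "Incremental effectiveness": None,
                "CER": self.cer_b,
                "ICER": None,
            },
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_rows())


def compare_values(
    cost_a: float,
    qaly_a: float,
    cost_b: float,
    qaly_b: float,
    wtp: WTPThreshold | float,
    label_a: str = "a",
    label_b: str = "b",
) -> CEAComparison:
    """Compare two strategies given their discounted totals.

    The ICER is ``delta_cost / delta_qaly`` and is undefined (``None``) when
    the arms are equally effective.  Arm a is deemed cost-effective versus b
    iff its net monetary benefit is strictly greater at the threshold; an
    exact NMB tie is resolved as not cost-effective, with a warning.
    """
    if qaly_a <= 0 or qaly_b <= 0:
        raise DomainError(f"QALY totals must be > 0, got {qaly_a} and {qaly_b}")
    threshold = wtp.threshold if isinstance(wtp, WTPThreshold) else float(wtp)
    if threshold < 0:
        raise DomainError(f"wtp must be >= 0, got {threshold}")
    delta_cost = cost_a - cost_b
    delta_qaly = qaly_a - qaly_b
    icer = delta_cost / delta_qaly if delta_qaly != 0 else None
    nmb_a = net_monetary_benefit(cost_a, qaly_a, threshold)
    nmb_b = net_monetary_benefit(cost_b, qaly_b, threshold)
    if nmb_a == nmb_b:
        logger.warning("%s vs %s: equal net monetary benefit at wtp %.0f; treating as not cost-effective",
                       label_a, label_b, threshold)
    return CEAComparison(
        label_a=label_a,
        label_b=label_b,
        cost_a=cost_a,
        cost_b=cost_b,
        qaly_a=qaly_a,
        qaly_b=qaly_b,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        cer_a=cost_a / qaly_a,
        cer_b=cost_b / qaly_b,
        icer=icer,
        dominance=_classify_dominance(delta_cost, delta_qaly),
        wtp=threshold,
        cost_effective=nmb_a > nmb_b,
    )


def compare_arms(
    result_a: ArmResult,
    result_b: ArmResult,
    wtp: WTPThreshold | float,
) -> CEAComparison:
    """Compare two simulated arms (see :func:`compare_values`)."""
    return compare_values(
        result_a.total_cost,
        result_a.total_qaly,
        result_b.total_cost,
        result_b.total_qaly,
        wtp,
        label_a=result_a.drug,
        label_b=result_b.drug,
    )


def decision_at_wtp(comparison: CEAComparison) -> bool:
    """Whether arm a is cost-effective versus arm b at the stored threshold."""
    return comparison.cost_effective
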