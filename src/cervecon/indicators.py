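"""Effectiveness metrics and the four per-arm economic indicators.

* CER — cost-effectiveness ratio: screening cost per confirmed positive.
* NPV — net present value: benefit minus cost; benefit is the treatment
  cost avoided by early detection (non-early minus early scenario).
* BCR — benefit-cost ratio: benefit / cost; an arm is cost-beneficial
  when NPV > 0 and BCR > 1 (the two are equivalent for positive cost).
* CUR — cost-utility ratio: screening cost per DALY averted.

Effectiveness rates: detection rate = confirmed / screened, positive
predictive value = confirmed / initial screen positives, colposcopy
referral rate = referred / screened (referrals are intentions; loss to
follow-up does not change denominators).  All reported as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .costs import round_half_up

__all__ = [
    "EffectivenessMetrics",
    "EconomicSummary",
    "detection_metrics",
    "benefit",
    "cer",
    "npv_bcr",
    "cur",
]


@dataclass(frozen=True)
class EffectivenessMetrics:
    n_screened: int
    n_initial_positive: int
    n_referred: int
    n_confirmed: int
    detection_rate: float  # percent
    positive_predictive_value: float  # percent
    referral_rate: float  # percent


def detection_metrics(
    n_screened: int,
    n_initial_positive: int,
    n_referred: int,
    n_confirmed: int,
) -> EffectivenessMetrics:
    """Compute the three effectiveness rates (percent) for one arm."""
    if not 0 <= n_confirmed <= n_initial_positive <= n_screened:
        raise ValueError(
            "counts must satisfy confirmed <= initial positives <= screened"
        )
    if n_screened == 0:
        raise ValueError("detection and referral rates undefined: n_screened is 0")
    if n_initial_positive == 0 and n_confirmed > 0:
        raise ValueError("positive predictive value undefined: no screen positives")
    ppv = (
        100.0 * n_confirmed / n_initial_positive if n_initial_positive else 0.0
    )
    return EffectivenessMetrics(
        n_screened=n_screened,
        n_initial_positive=n_initial_positive,
        n_referred=n_referred,
        n_confirmed=n_confirmed,
        detection_rate=100.0 * n_confirmed / n_screened,
        positive_predictive_value=ppv,
        referral_rate=100.0 * n_referred / n_screened,
    )


def benefit(non_early_total: float, early_total: float) -> float:
    """Treatment cost avoided by early detection (may be negative)."""
    if non_early_total < 0 or early_total < 0:
        raise ValueError("costs must be non-negative")
    return non_early_total - early_total


def cer(cost: float, n_confirmed: int) -> float:
    """Screening cost per confirmed positive case."""
    if n_confirmed <= 0:
        raise ValueError("CER undefined for zero confirmed positives")
    return cost / n_confirmed


def npv_bcr(benefit_value: float, cost: float) -> tuple[float, float]:
    """(net present value, benefit-cost ratio) of one arm."""
    if cost <= 0:
        raise ValueError("NPV/BCR require a positive cost")
    return benefit_value - cost, benefit_value / cost


def cur(cost: float, dalys: float) -> float:
    """Screening cost per DALY averted."""
    if dalys <= 0:
        raise ValueError("CUR undefined for non-positive DALYs averted")
    return cost / dalys


@dataclass(frozen=True)
class EconomicSummary:
    """One arm's costs, effectiveness, and economic indicators."""

    arm: str
    cost: float
    benefit: float
    dalys: float
    metrics: EffectivenessMetrics
    daly_source: str = "computed"  # "reference" or "computed"
    computed_dalys: Optional[float] = None

    @property
    def cer(self) -> float:
        return cer(self.cost, self.metrics.n_confirmed)

    @property
    def npv(self) -> float:
        return npv_bcr(self.benefit, self.cost)[0]

    @property
    def bcr(self) -> float:
        return npv_bcr(self.benefit, self.cost)[1]

    @property
    def cur(self) -> float:
        return cur(self.cost, self.dalys)

    @property
    def cost_beneficial(self) -> bool:
        return self.npv > 0 and self.bcr > 1

    def reported(self) -> dict:
        """Rounded row: money 0.1 RMB, rates 2 dp, BCR 2 dp, DALYs 3 dp."""
        m = self.metrics
        return {
            "arm": self.arm,
            "cost": round_half_up(self.cost, 1),
            "detection_rate_pct": round_half_up(m.detection_rate, 2),
            "ppv_pct": round_half_up(m.positive_predictive_value, 2),
            "referral_rate_pct": round_half_up(m.referral_rate, 2),
            "cer": round_half_up(self.cer, 1),
            "benefit": round_half_up(self.benefit, 1),
            "npv": round_half_up(self.npv, 1),
            "bcr": round_half_up(self.bcr, 2),
            "dalys": round_half_up(self.dalys, 3),
            "cur": round_half_up(self.cur, 1),
            "daly_source": self.daly_source,
            "cost_beneficial": self.cost_beneficial,
        }
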