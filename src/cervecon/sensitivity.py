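"""Univariate sensitivity analysis over the evaluation pipeline.

One parameter is perturbed at a time and the whole pipeline re-run; the
report gives, per arm and indicator (CER, NPV, BCR, CUR), the baseline
value, the perturbed value, and the variation ratio
``(perturbed - baseline) / baseline``, plus normalized perturbed /
baseline curves and a ranking check (does the VIA/VILI arm stay best on
all four indicators?).

Supported parameters:

* ``radiochemo_cost`` — multiplicative: cost -> cost * (1 + delta);
* ``discount_rate_gamma`` — additive in percentage points: 0.03 with
  delta 0.01 becomes 0.04.  Gamma feeds the DALY discounting, so for
  this parameter CUR is recomputed from the model's own counterfactual
  burden in both the baseline and perturbed runs (reference DALY totals
  are external constants and cannot respond to gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ScreeningEvaluation

__all__ = ["SensitivityResult", "perturb", "univariate_sweep"]

PARAMETERS = ("radiochemo_cost", "discount_rate_gamma")
INDICATORS = ("cer", "npv", "bcr", "cur")

#: indicators where "best" is the smallest value
LOWER_IS_BETTER = {"cer": True, "npv": False, "bcr": False, "cur": True}


def perturb(
    model: ScreeningEvaluation, parameter: str, rel_delta: float
) -> ScreeningEvaluation:
    """A copy of the model with one parameter perturbed.

    ``radiochemo_cost`` scales multiplicatively by (1 + rel_delta);
    ``discount_rate_gamma`` shifts additively by rel_delta (percentage
    points expressed as a fraction, 0.01 = one point).
    """
    if parameter == "radiochemo_cost":
        new = model.unit_costs.radiochemo_cost * (1.0 + rel_delta)
        if new < 0:
            raise ValueError("perturbed radiochemo cost is negative")
        return model.replace(unit_costs=model.unit_costs.replace(radiochemo_cost=new))
    if parameter == "discount_rate_gamma":
        new = model.daly_params.gamma + rel_delta
        if new < 0:
            raise ValueError("perturbed discount rate is negative")
        return model.replace(
            daly_params=model.daly_params.replace(gamma=new),
            unit_costs=model.unit_costs.replace(discount_rate=new),
        )
    raise ValueError(
        f"unknown sensitivity parameter {parameter!r}; expected one of {PARAMETERS}"
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Long-format sweep table plus per-indicator maxima and ranking."""

    parameter: str
    deltas: tuple[float, ...]
    table: pd.DataFrame  # arm, indicator, delta, baseline, perturbed, variation
    reference_arm: str

    @property
    def max_abs_variation(self) -> dict[str, float]:
        """Max |variation ratio| per indicator across arms and deltas."""
        out = {}
        for ind in INDICATORS:
            sub = self.table[self.table["indicator"] == ind]
            out[ind] = float(sub["variation"].abs().max()) if len(sub) else 0.0
        return out

    @property
    def ranking_stable(self) -> bool:
        """True if the reference arm is best on every indicator at every delta."""
        for delta in self.deltas:
            sub = self.table[self.table["delta"] == delta]
            for ind in INDICATORS:
                vals = sub[sub["indicator"] == ind].set_index("arm")["perturbed"]
                best = vals.idxmin() if LOWER_IS_BETTER[ind] else vals.idxmax()
                if best != self.reference_arm:
                    return False
        return True

    def normalized_curves(self) -> pd.DataFrame:
        """Perturbed / baseline ratio per (arm, indicator, delta)."""
        df = self.table.copy()
        df["ratio"] = df["perturbed"] / df["baseline"]
        return df[["arm", "indicator", "delta", "ratio"]]


def _indicator_values(result, gamma_mode: bool) -> pd.DataFrame:
    rows = []
    for a in result.arm_names:
        s = result.summaries[a]
        dalys = s.computed_dalys if gamma_mode else s.dalys
        rows.append(
            {
                "arm": a,
                "cer": s.cer,
                "npv": s.npv,
                "bcr": s.bcr,
                "cur": s.cost / dalys,
            }
        )
    return pd.DataFrame(rows).set_index("arm")


def univariate_sweep(
    model: ScreeningEvaluation,
    parameter: str,
    deltas,
    reference_arm: str = "VIA_VILI",
) -> SensitivityResult:
    """Re-run the pipeline once per delta and tabulate variation ratios.

    A pipeline failure at any delta aborts with the offending delta
    named.  For ``discount_rate_gamma`` the CUR rows use the model's
    computed DALY burden on both sides of the ratio (see module
    docstring).
    """
    deltas = tuple(float(d) for d in deltas)
    gamma_mode = parameter == "discount_rate_gamma"
    base_model = model
    if gamma_mode and model.life_table is None:
        raise ValueError("discount-rate sweep needs a life table (computed DALYs)")
    baseline = _indicator_values(base_model.fit(), gamma_mode)
    rows = []
    for delta in deltas:
        try:
            pert = _indicator_values(perturb(model, parameter, delta).fit(), gamma_mode)
        except Exception as exc:
            raise RuntimeError(
                f"sensitivity pipeline failed at delta {delta:+g}: {exc}"
            ) from exc
        for a in baseline.index:
            for ind in INDICATORS:
                b = baseline.loc[a, ind]
                p = pert.loc[a, ind]
                rows.append(
                    {
                        "arm": a,
                        "indicator": ind,
                        "delta": delta,
                        "baseline": b,
                        "perturbed": p,
                        "variation": (p - b) / b if b != 0 else np.nan,
                    }
                )
    return SensitivityResult(
        parameter=parameter,
        deltas=deltas,
        table=pd.DataFrame(rows),
        reference_arm=reference_arm,
    )
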