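"""Model/Results objects orchestrating the full evaluation pipeline.

:class:`ScreeningEvaluation` is built from the evaluation's inputs (arm
aggregates, screening cost components, unit-cost schedule, transition
matrix, DALY parameters, life table) and :meth:`~ScreeningEvaluation.fit`
runs the whole chain — screening costing, early / non-early treatment
costing, counterfactual Markov burden, effectiveness metrics and the
four economic indicators — returning an :class:`EvaluationResults` that
carries the three report tables, the per-year burden series, pooled
cohort trajectories and a ``summary()``.

Construct from the bundled study calibration with
:meth:`ScreeningEvaluation.from_profile`, or from per-woman screening
records (e.g. the synthetic cohort generator's output) with
:meth:`ScreeningEvaluation.from_records`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .costs import (
    CaseMix,
    ScreeningCostTable,
    UnitCostSchedule,
    early_treatment_cost,
    non_early_treatment_cost,
    round_half_up,
    screening_total,
)
from .daly import BurdenResult, DalyParams, LifeTable, averted_dalys
from .indicators import EconomicSummary, benefit, detection_metrics
from .markov import CohortTrajectory, TransitionMatrix, simulate
from .states import HealthState, N_STATES

__all__ = ["ArmData", "ScreeningEvaluation", "EvaluationResults"]

#: GDP-per-capita benchmark (RMB, 2014) used only as a report annotation
#: for the cost-utility threshold ("very cost-effective" when CUR < GDP
#: per capita).
GDP_PER_CAPITA_RMB = 49886.8


@dataclass(frozen=True)
class ArmData:
    """Aggregated screening outcomes of one trial arm."""

    name: str
    n_screened: int
    n_initial_positive: int
    n_referred: int
    case_mix: CaseMix
    reference_dalys: Optional[float] = None

    @property
    def n_confirmed(self) -> int:
        return self.case_mix.total


class ScreeningEvaluation:
    """Health-economic evaluation model for a multi-arm screening trial.

    Parameters
    ----------
    arms
        Per-arm aggregates (counts and confirmed case mix).
    screening_components
        DataFrame indexed by component name with one cost column per arm
        (blank = not applicable) and an optional ``stage`` column.
    unit_costs, matrix, daly_params, life_table
        The costing schedule, annual transition matrix, DALY constants
        and residual-expectancy table.  ``life_table`` may be omitted
        only when ``daly_source="reference"`` and every arm carries a
        reference DALY total.
    start_age
        Age at which confirmed cases enter the natural-history model.
    horizon
        Number of annual Markov cycles (default 15).
    daly_source
        ``"computed"`` — CUR uses the model's own counterfactual burden;
        ``"reference"`` — CUR uses the arms' reference DALY totals
        (externally supplied, life-table-dependent figures).
    """

    def __init__(
        self,
        arms: Sequence[ArmData],
        screening_components: pd.DataFrame,
        unit_costs: UnitCostSchedule,
        matrix: TransitionMatrix,
        daly_params: DalyParams,
        life_table: Optional[LifeTable],
        start_age: float,
        horizon: int = 15,
        daly_source: str = "computed",
    ):
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        if daly_source not in ("computed", "reference"):
            raise ValueError("daly_source must be 'computed' or 'reference'")
        if daly_source == "reference":
            missing = [a.name for a in arms if a.reference_dalys is None]
            if missing:
                raise ValueError(
                    f"daly_source='reference' but arms {missing} carry no "
                    "reference DALY total"
                )
        if life_table is None and daly_source == "computed":
            raise ValueError(
                "missing input: life table (required to compute YLL when "
                "daly_source='computed')"
            )
        for a in arms:
            if a.name not in screening_components.columns:
                raise ValueError(
                    f"missing input: screening cost column for arm {a.name!r}"
                )
        self.arms = list(arms)
        self.screening_components = screening_components
        self.unit_costs = unit_costs
        self.matrix = matrix
        self.daly_params = daly_params
        self.life_table = life_table
        self.start_age = float(start_age)
        self.horizon = int(horizon)
        self.daly_source = daly_source

    # -- constructors -------------------------------------------------

    @classmethod
    def from_profile(cls, name: str = "study", **overrides) -> "ScreeningEvaluation":
        """Build the model from the bundled study calibration."""
        from . import profiles

        if name != "study":
            raise ValueError(f"unknown profile {name!r}")
        raw = profiles.load_arm_aggregates()
        arms = [
            ArmData(
                name=a["name"],
                n_screened=a["n_screened"],
                n_initial_positive=a["n_initial_positive"],
                n_referred=a["n_referred"],
                case_mix=CaseMix(a["case_mix"]),
                reference_dalys=a.get("reference_dalys"),
            )
            for a in raw["arms"]
        ]
        kwargs = dict(
            arms=arms,
            screening_components=profiles.load_screening_table(),
            unit_costs=profiles.load_unit_costs(),
            matrix=profiles.load_transition_matrix(),
            daly_params=profiles.load_daly_params(),
            life_table=profiles.load_life_table(),
            start_age=raw.get("start_age", 45),
            horizon=raw.get("horizon", 15),
            daly_source="reference",
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        reference_dalys: Optional[Mapping[str, float]] = None,
        **overrides,
    ) -> "ScreeningEvaluation":
        """Build the model from per-woman screening records.

        Records are aggregated per arm (see
        :func:`cervecon.cohort.aggregate`); every other input defaults
        to the bundled study calibration and can be overridden.
        """
        from . import profiles
        from .cohort import aggregate

        agg = aggregate(records)
        ref = dict(reference_dalys or {})
        arms = [
            ArmData(
                name=row["arm"],
                n_screened=row["n_screened"],
                n_initial_positive=row["n_initial_positive"],
                n_referred=row["n_referred"],
                case_mix=row["case_mix"],
                reference_dalys=ref.get(row["arm"]),
            )
            for _, row in agg.iterrows()
        ]
        raw = profiles.load_arm_aggregates()
        kwargs = dict(
            arms=arms,
            screening_components=profiles.load_screening_table(),
            unit_costs=profiles.load_unit_costs(),
            matrix=profiles.load_transition_matrix(),
            daly_params=profiles.load_daly_params(),
            life_table=profiles.load_life_table(),
            start_age=raw.get("start_age", 45),
            horizon=raw.get("horizon", 15),
            daly_source="reference" if ref else "computed",
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def replace(self, **changes) -> "ScreeningEvaluation":
        """A copy of the model with the given attributes swapped."""
        kwargs = dict(
            arms=self.arms,
            screening_components=self.screening_components,
            unit_costs=self.unit_costs,
            matrix=self.matrix,
            daly_params=self.daly_params,
            life_table=self.life_table,
            start_age=self.start_age,
            horizon=self.horizon,
            daly_source=self.daly_source,
        )
        kwargs.update(changes)
        return ScreeningEvaluation(**kwargs)

    # -- fitting ------------------------------------------------------

    def config_hash(self) -> str:
        """Deterministic digest of every model input (provenance tag)."""
        payload = {
            "arms": [
                {
                    "name": a.name,
                    "n_screened": a.n_screened,
                    "n_initial_positive": a.n_initial_positive,
                    "n_referred": a.n_referred,
                    "case_mix": {g.name: n for g, n in a.case_mix.items()},
                    "reference_dalys": a.reference_dalys,
                }
                for a in self.arms
            ],
            "screening_components": self.screening_components.fillna("").to_dict(),
            "unit_costs": {
                "surgery": {g.name: v for g, v in self.unit_costs.surgery_cost.items()},
                "radiochemo": self.unit_costs.radiochemo_cost,
                "per_diem": [
                    self.unit_costs.diet,
                    self.unit_costs.accommodation,
                    self.unit_costs.transport_comm,
                    self.unit_costs.wage,
                ],
                "stay": {g.name: v for g, v in self.unit_costs.stay_days.items()},
                "companion": [self.unit_costs.diet_persons, self.unit_costs.wage_persons],
                "discount_rate": self.unit_costs.discount_rate,
            },
            "matrix": self.matrix.probs.tolist(),
            "daly": {
                "gamma": self.daly_params.gamma,
                "beta": self.daly_params.beta,
                "C": self.daly_params.C,
                "weights": {
                    s.name: w for s, w in self.daly_params.disability_weights.items()
                },
            },
            "life_table": (
                None
                if self.life_table is None
                else [self.life_table.ages.tolist(),
                      self.life_table.expectancies.tolist()]
            ),
            "start_age": self.start_age,
            "horizon": self.horizon,
            "daly_source": self.daly_source,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def fit(self) -> "EvaluationResults":
        """Run the full pipeline and return the results object."""
        screening: dict[str, ScreeningCostTable] = {}
        early = {}
        non_early = {}
        burden: dict[str, BurdenResult] = {}
        trajectories: dict[str, CohortTrajectory] = {}
        summaries: dict[str, EconomicSummary] = {}

        for arm in self.arms:
            comp = self.screening_components[arm.name].to_dict()
            scr = screening_total(comp, arm.n_screened)
            screening[arm.name] = scr
            e = early_treatment_cost(arm.case_mix, self.unit_costs)
            ne = non_early_treatment_cost(arm.case_mix, self.unit_costs)
            early[arm.name] = e
            non_early[arm.name] = ne
            # reported (rounded-cell) treatment totals feed benefit, so the
            # indicator chain reproduces tabulated figures exactly
            e_total = e.reported()["total"]
            ne_total = ne.reported()["total"]
            arm_benefit = benefit(ne_total, e_total)

            computed = None
            if self.life_table is not None:
                b = averted_dalys(
                    arm.case_mix,
                    self.matrix,
                    self.daly_params,
                    self.life_table,
                    start_age=self.start_age,
                    n_cycles=self.horizon,
                )
                burden[arm.name] = b
                computed = b.total_daly
                dist0 = np.zeros(N_STATES)
                for g, n in arm.case_mix.items():
                    dist0[g] = n
                trajectories[arm.name] = simulate(
                    dist0, self.matrix, self.horizon, self.start_age
                )
            dalys = (
                arm.reference_dalys
                if self.daly_source == "reference"
                else computed
            )
            cost = round_half_up(scr.total, 1)
            summaries[arm.name] = EconomicSummary(
                arm=arm.name,
                cost=cost,
                benefit=arm_benefit,
                dalys=dalys,
                metrics=detection_metrics(
                    arm.n_screened,
                    arm.n_initial_positive,
                    arm.n_referred,
                    arm.n_confirmed,
                ),
                daly_source=self.daly_source,
                computed_dalys=computed,
            )
        return EvaluationResults(
            model=self,
            screening=screening,
            early=early,
            non_early=non_early,
            burden=burden,
            trajectories=trajectories,
            summaries=summaries,
        )


class EvaluationResults:
    """Fitted evaluation: report tables, burden series and summaries."""

    def __init__(self, model, screening, early, non_early, burden,
                 trajectories, summaries):
        self.model = model
        self.screening = screening
        self.early = early
        self.non_early = non_early
        self.burden = burden
        self.trajectories = trajectories
        self.summaries = summaries
        self.config_hash = model.config_hash()

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.model.arms]

    # -- tables -------------------------------------------------------

    def screening_costs(self) -> pd.DataFrame:
        """Per-component screening costs per arm, with Total/per-capita."""
        df = self.model.screening_components[self.arm_names].copy()
        totals = {a: round_half_up(self.screening[a].total, 1) for a in self.arm_names}
        per_cap = {a: round_half_up(self.screening[a].per_capita, 1)
                   for a in self.arm_names}
        df.loc["Total"] = pd.Series(totals)
        df.loc["Per capita"] = pd.Series(per_cap)
        return df

    def treatment_costs(self) -> pd.DataFrame:
        """Early / non-early treatment cost breakdown per arm (rounded)."""
        rows = []
        for scenario, table in (("early", self.early), ("non_early", self.non_early)):
            for field in ("direct_medical", "direct_non_medical", "indirect", "total"):
                row = {"scenario": scenario, "cost": field}
                for a in self.arm_names:
                    row[a] = table[a].reported()[field]
                rows.append(row)
        return pd.DataFrame(rows).set_index(["scenario", "cost"])

    def economic(self) -> pd.DataFrame:
        """Per-arm effectiveness and indicator table (rounded)."""
        rows = [self.summaries[a].reported() for a in self.arm_names]
        df = pd.DataFrame(rows).set_index("arm")
        df["cur_below_gdp_per_capita"] = df["cur"] < GDP_PER_CAPITA_RMB
        return df

    def burden_series(self) -> pd.DataFrame:
        """Per-arm, per-year averted YLD / YLL / DALY (long format)."""
        frames = []
        for a, b in self.burden.items():
            df = b.to_dataframe()
            df.insert(0, "arm", a)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["arm", "year", "yld", "yll", "daly"])
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable run summary (economic table + provenance)."""
        lines = [
            "Screening health-economic evaluation",
            f"  arms: {', '.join(self.arm_names)}  "
            f"horizon: {self.model.horizon} y  start age: {self.model.start_age}",
            f"  DALY denominators: {self.model.daly_source} "
            "(life-table-dependent)",
            f"  config hash: {self.config_hash}",
            "",
            self.economic().to_string(),
            "",
            "cost-beneficial arms (NPV > 0 and BCR > 1): "
            + (", ".join(a for a in self.arm_names
                         if self.summaries[a].cost_beneficial) or "none"),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write the CSV/JSON report bundle; returns the paths written.

        Deterministic: identical inputs give byte-identical files, each
        JSON carrying the config hash.
        """
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _csv(name, df, **kw):
            p = out / f"{name}.csv"
            df.to_csv(p, **kw)
            paths[name] = p

        _csv("screening_costs", self.screening_costs())
        _csv("treatment_costs", self.treatment_costs())
        _csv("economic", self.economic())
        _csv("burden_series", self.burden_series(), index=False)
        for a, traj in self.trajectories.items():
            _csv(f"trajectory_{a}", traj.to_dataframe(), index=False)

        bundle = {
            "config_hash": self.config_hash,
            "daly_source": self.model.daly_source,
            "note": "DALY-dependent outputs are life-table-dependent",
            "screening_totals": {
                a: round_half_up(self.screening[a].total, 1) for a in self.arm_names
            },
            "treatment_costs": {
                a: {
                    "early": self.early[a].reported(),
                    "non_early": self.non_early[a].reported(),
                }
                for a in self.arm_names
            },
            "economic": {
                a: self.summaries[a].reported() for a in self.arm_names
            },
        }
        p = out / "evaluation.json"
        p.write_text(json.dumps(bundle, indent=2, sort_keys=True))
        paths["evaluation"] = p

        log = out / "run_log.json"
        log.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "stages": [
                        "screening_costing",
                        "treatment_costing",
                        "markov_burden",
                        "indicators",
                    ],
                    "outputs": {k: str(v) for k, v in paths.items()},
                },
                indent=2,
                sort_keys=True,
            )
        )
        paths["run_log"] = log
        return paths
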