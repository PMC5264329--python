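"""Screening and treatment costing.

Costs split into direct medical cost (surgery tariffs per lesion grade
plus radiotherapy/chemotherapy for cancer), direct non-medical cost
(diet, accommodation, transport/communication per hospital day) and
indirect cost (workforce-productivity loss).  Social per-diem rates are
applied per hospital day with companion multipliers: two persons eat and
two daily wages are lost per day (patient plus one companion), lodging
and transport are counted once.

Two treatment scenarios are costed per arm:

* early: each confirmed case is managed at its diagnosed grade — surgery
  for CIN2/CIN3, surgery plus radiochemotherapy for cancer, follow-up
  only (costless here) for CIN1;
* non-early: the counterfactual in which every case of grade >= CIN2
  goes untreated, develops invasive cancer, and is costed as a full
  cancer case.

The benefit of a screening arm is the non-early minus early total.
Internal arithmetic is unrounded; reported tables round half-up to 0.1
RMB at the reporting layer only (totals are sums of rounded components,
matching the convention of the source tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Mapping

import pandas as pd
import yaml

from .states import GRADES, HealthState, TREATED_GRADES, as_state

__all__ = [
    "round_half_up",
    "UnitCostSchedule",
    "CaseMix",
    "ScreeningCostTable",
    "TreatmentCostBreakdown",
    "screening_total",
    "hospitalization_days",
    "social_cost",
    "early_treatment_cost",
    "non_early_treatment_cost",
    "discount",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Binary floats representing exact decimal products (e.g. 12.3 * 23.5
    = 289.05) can sit a hair below the true value, so the number is
    first snapped to 6 decimals before the final rounding; all monetary
    inputs here carry at most one decimal, making 6 digits safely exact.
    """
    snapped = Decimal(repr(float(x))).quantize(Decimal("1e-6"), ROUND_HALF_UP)
    q = Decimal(1).scaleb(-ndigits)
    return float(snapped.quantize(q, ROUND_HALF_UP))


@dataclass(frozen=True)
class UnitCostSchedule:
    """Unit treatment costs, per-diem social rates and stay durations.

    Defaults are the study calibration (2014 RMB): government surgery
    tariffs 2400 / 5650 / 8500 RMB for CIN2 / CIN3 / cancer,
    radiotherapy+chemotherapy 54823.3 RMB per cancer case, hospital
    stays 5.8 / 7.5 / 12.3 / 26.3 days for CIN1..cancer, and yearbook
    per-diems (diet 8.5, accommodation 3.7, transport/communication 2.8,
    wage 93.8 RMB/day).
    """

    surgery_cost: Mapping[HealthState, float] = field(
        default_factory=lambda: {
            HealthState.CIN2: 2400.0,
            HealthState.CIN3: 5650.0,
            HealthState.CANCER: 8500.0,
        }
    )
    radiochemo_cost: float = 54823.3
    diet: float = 8.5
    accommodation: float = 3.7
    transport_comm: float = 2.8
    wage: float = 93.8
    stay_days: Mapping[HealthState, float] = field(
        default_factory=lambda: {
            HealthState.CIN1: 5.8,
            HealthState.CIN2: 7.5,
            HealthState.CIN3: 12.3,
            HealthState.CANCER: 26.3,
        }
    )
    diet_persons: int = 2   # patient + companion meals per day
    wage_persons: int = 2   # daily wages lost per hospital day
    discount_rate: float = 0.03

    def __post_init__(self):
        object.__setattr__(
            self,
            "surgery_cost",
            {as_state(k): float(v) for k, v in self.surgery_cost.items()},
        )
        object.__setattr__(
            self,
            "stay_days",
            {as_state(k): float(v) for k, v in self.stay_days.items()},
        )
        for name in (
            "radiochemo_cost", "diet", "accommodation", "transport_comm",
            "wage", "discount_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for m in (self.surgery_cost, self.stay_days):
            for s, v in m.items():
                if s not in GRADES:
                    raise ValueError(f"{s.name} is not a pathology grade")
                if v < 0:
                    raise ValueError(f"negative value for grade {s.name}")

    @property
    def daily_nonmedical_rate(self) -> float:
        """RMB per hospital day of diet + lodging + transport/comm."""
        return (
            self.diet_persons * self.diet
            + self.accommodation
            + self.transport_comm
        )

    @property
    def daily_indirect_rate(self) -> float:
        """RMB of productivity loss per hospital day."""
        return self.wage * self.wage_persons

    @classmethod
    def from_yaml(cls, path) -> "UnitCostSchedule":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pd_ = raw.get("per_diem", {})
        comp = raw.get("companion", {})
        return cls(
            surgery_cost=raw["surgery_cost"],
            radiochemo_cost=raw["radiochemo_cost"],
            diet=pd_.get("diet", 8.5),
            accommodation=pd_.get("accommodation", 3.7),
            transport_comm=pd_.get("transport_comm", 2.8),
            wage=pd_.get("wage", 93.8),
            stay_days=raw["stay_days"],
            diet_persons=comp.get("diet_persons", 2),
            wage_persons=comp.get("wage_persons", 2),
            discount_rate=raw.get("discount_rate", 0.03),
        )

    def replace(self, **changes) -> "UnitCostSchedule":
        kw = dict(
            surgery_cost=dict(self.surgery_cost),
            radiochemo_cost=self.radiochemo_cost,
            diet=self.diet,
            accommodation=self.accommodation,
            transport_comm=self.transport_comm,
            wage=self.wage,
            stay_days=dict(self.stay_days),
            diet_persons=self.diet_persons,
            wage_persons=self.wage_persons,
            discount_rate=self.discount_rate,
        )
        kw.update(changes)
        return UnitCostSchedule(**kw)


class CaseMix(Mapping):
    """Confirmed-positive counts by pathology grade for one arm."""

    def __init__(self, counts: Mapping):
        c: dict[HealthState, int] = {}
        for grade, n in counts.items():
            s = as_state(grade)
            if s not in GRADES:
                raise ValueError(f"{s.name} is not a pathology grade")
            if n < 0:
                raise ValueError(f"negative case count for {s.name}")
            if n:
                c[s] = c.get(s, 0) + int(n)
        self._counts = c

    def __getitem__(self, grade) -> int:
        return self._counts.get(as_state(grade), 0)

    def __iter__(self) -> Iterator[HealthState]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    @property
    def total(self) -> int:
        return sum(self._counts.values())

    @property
    def n_treated(self) -> int:
        """Cases of grade >= CIN2 (surgically managed)."""
        return sum(n for g, n in self._counts.items() if g in TREATED_GRADES)

    def __add__(self, other: "CaseMix") -> "CaseMix":
        merged = dict(self._counts)
        for g, n in other._counts.items():
            merged[g] = merged.get(g, 0) + n
        return CaseMix(merged)

    def __repr__(self) -> str:
        inner = ", ".join(f"{g.name}: {n}" for g, n in self._counts.items())
        return f"CaseMix({{{inner}}})"


@dataclass(frozen=True)
class ScreeningCostTable:
    """Per-arm screening cost components with total and per-capita."""

    components: Mapping[str, float]
    arm_size: int

    def __post_init__(self):
        if self.arm_size <= 0:
            raise ValueError("arm_size must be positive")
        for name, v in self.components.items():
            if v < 0:
                raise ValueError(f"negative screening component {name!r}")

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    @property
    def per_capita(self) -> float:
        return self.total / self.arm_size


def screening_total(components: Mapping[str, float], arm_size: int) -> ScreeningCostTable:
    """Assemble a screening cost table; missing components (NaN) dropped."""
    clean = {
        k: float(v)
        for k, v in components.items()
        if v is not None and v == v  # drops NaN
    }
    return ScreeningCostTable(components=clean, arm_size=arm_size)


@dataclass(frozen=True)
class TreatmentCostBreakdown:
    """Direct medical / direct non-medical / indirect treatment costs."""

    direct_medical: float
    direct_non_medical: float
    indirect: float

    def __post_init__(self):
        for f in ("direct_medical", "direct_non_medical", "indirect"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def total(self) -> float:
        return self.direct_medical + self.direct_non_medical + self.indirect

    def reported(self) -> dict[str, float]:
        """Rounded (half-up, 0.1 RMB) cells; total = sum of rounded parts."""
        dm = round_half_up(self.direct_medical)
        dn = round_half_up(self.direct_non_medical)
        ind = round_half_up(self.indirect)
        return {
            "direct_medical": dm,
            "direct_non_medical": dn,
            "indirect": ind,
            "total": round_half_up(dm + dn + ind),
        }


def hospitalization_days(case_mix: Mapping, schedule: UnitCostSchedule) -> float:
    """Total hospital days of a case mix: sum of count x stay(grade)."""
    days = 0.0
    for grade, n in case_mix.items():
        s = as_state(grade)
        if s not in schedule.stay_days:
            raise KeyError(f"no hospitalization duration for grade {s.name}")
        days += n * schedule.stay_days[s]
    return days


def social_cost(days: float, schedule: UnitCostSchedule) -> tuple[float, float]:
    """(direct non-medical, indirect) social cost of ``days`` hospital days."""
    if days < 0:
        raise ValueError("days must be non-negative")
    return (
        days * schedule.daily_nonmedical_rate,
        days * schedule.daily_indirect_rate,
    )


def early_treatment_cost(
    case_mix: CaseMix, schedule: UnitCostSchedule
) -> TreatmentCostBreakdown:
    """Cost of treating each confirmed case at its diagnosed grade.

    CIN2/CIN3 incur their surgery tariff; cancer incurs surgery plus
    radiochemotherapy; CIN1 receives follow-up only and is costless.
    Social costs accrue over the hospital days of grades >= CIN2.
    """
    direct_medical = 0.0
    days = 0.0
    for g in TREATED_GRADES:
        n = case_mix[g]
        if not n:
            continue
        direct_medical += n * schedule.surgery_cost[g]
        if g is HealthState.CANCER:
            direct_medical += n * schedule.radiochemo_cost
        days += n * schedule.stay_days[g]
    dnm, indirect = social_cost(days, schedule)
    return TreatmentCostBreakdown(direct_medical, dnm, indirect)


def non_early_treatment_cost(
    case_mix: CaseMix, schedule: UnitCostSchedule
) -> TreatmentCostBreakdown:
    """Counterfactual cost: every >= CIN2 case becomes one cancer case.

    Untreated high-grade lesions are assumed to progress to invasive
    cancer; each is costed as cancer surgery plus radiochemotherapy with
    a cancer-length hospital stay.  CIN1 cases are excluded.
    """
    n = case_mix.n_treated
    direct_medical = n * (
        schedule.surgery_cost[HealthState.CANCER] + schedule.radiochemo_cost
    )
    dnm, indirect = social_cost(
        n * schedule.stay_days[HealthState.CANCER], schedule
    )
    return TreatmentCostBreakdown(direct_medical, dnm, indirect)


def discount(amount: float, years: float, rate: float) -> float:
    """Present value of ``amount`` due ``years`` ahead at annual ``rate``."""
    if rate < 0 or years < 0:
        raise ValueError("rate and years must be non-negative")
    return amount / (1.0 + rate) ** years


def load_screening_components(path) -> pd.DataFrame:
    """Read the per-component, per-arm screening cost CSV (Table-1 layout).

    One row per cost component with a ``stage`` label, one column per
    arm; blank cells mean the component does not apply to that arm.
    """
    df = pd.read_csv(path)
    if "component" not in df.columns:
        raise ValueError("screening component CSV needs a 'component' column")
    return df.set_index("component")
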