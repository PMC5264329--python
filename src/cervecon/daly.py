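"""Age-weighted, discounted burden-of-disease metrics (YLL, YLD, DALY).

A year lived at age ``x`` is weighted ``C * x * exp(-beta * x)`` (the
GBD-1996 age-weighting convention) and future years are continuously
discounted at the social rate ``gamma``.  The burden of living with a
condition of disability weight ``D`` from onset age ``alpha`` for ``L``
years is then

    burden = integral_0^L  D * C * (alpha + x) * exp(-beta*(alpha+x))
                              * exp(-gamma*x) dx,

which has the closed form implemented by :func:`murray_burden` (with
``D = 1`` and ``L`` the residual life expectancy at death it yields the
YLL of one death; with a state's disability weight and ``L`` a year of
occupancy it yields YLD).  Cohort-level series are accumulated from a
Markov trajectory: one burden term per state and follow-up year, at the
age then current.

All outputs depend on the bundled female residual-life-expectancy table
(replaceable data, see :class:`LifeTable`); results are therefore
flagged life-table-dependent in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .markov import CohortTrajectory, TransitionMatrix, incident_deaths, simulate
from .states import HealthState, as_state

__all__ = [
    "DalyParams",
    "LifeTable",
    "BurdenResult",
    "murray_burden",
    "yld_from_trajectory",
    "yll_from_deaths",
    "averted_dalys",
]

#: disability weights of the study calibration
DEFAULT_WEIGHTS: dict[HealthState, float] = {
    HealthState.UNTESTED: 0.0,
    HealthState.HPV_INFECTION: 0.0,
    HealthState.CIN1: 0.0,
    HealthState.CIN2: 0.1238,
    HealthState.CIN3: 0.1941,
    HealthState.CANCER: 0.307,
    HealthState.DEAD: 1.0,
}


@dataclass(frozen=True)
class DalyParams:
    """DALY constants: discount rate, age weighting, disability weights.

    ``C = 0.1658`` is the study's age-weighting correction constant
    (the common GBD value is 0.16243; both are supported as data).
    """

    gamma: float = 0.03
    beta: float = 0.04
    C: float = 0.1658
    disability_weights: Mapping[HealthState, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )

    def __post_init__(self):
        if self.gamma < 0 or self.beta < 0:
            raise ValueError("gamma and beta must be non-negative")
        if self.C <= 0:
            raise ValueError("C must be positive")
        w = {as_state(k): float(v) for k, v in self.disability_weights.items()}
        for s, v in w.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"disability weight for {s.name} outside [0,1]")
        if w.get(HealthState.DEAD, 1.0) != 1.0:
            raise ValueError("DEAD must carry disability weight 1")
        for s in (HealthState.UNTESTED, HealthState.HPV_INFECTION, HealthState.CIN1):
            if w.get(s, 0.0) != 0.0:
                raise ValueError(f"{s.name} must carry disability weight 0")
        object.__setattr__(self, "disability_weights", w)

    def weight(self, state) -> float:
        s = as_state(state)
        try:
            return self.disability_weights[s]
        except KeyError:
            raise KeyError(f"no disability weight configured for {s.name}") from None

    @classmethod
    def from_yaml(cls, path) -> "DalyParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            gamma=raw["gamma"],
            beta=raw["beta"],
            C=raw["C"],
            disability_weights=raw["disability_weights"],
        )

    def replace(self, **changes) -> "DalyParams":
        kw = dict(
            gamma=self.gamma,
            beta=self.beta,
            C=self.C,
            disability_weights=dict(self.disability_weights),
        )
        kw.update(changes)
        return DalyParams(**kw)


@dataclass(frozen=True)
class LifeTable:
    """Female residual life expectancy by age, linearly interpolated.

    Ages must be strictly increasing and expectancies positive and
    non-increasing.  Lookups outside the tabulated age range raise
    (no extrapolation).
    """

    ages: np.ndarray
    expectancies: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.ages, dtype=float)
        e = np.asarray(self.expectancies, dtype=float)
        if a.ndim != 1 or a.shape != e.shape or a.size < 2:
            raise ValueError("life table needs matching 1-d age/expectancy arrays")
        if np.any(np.diff(a) <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        if np.any(e <= 0) or np.any(np.diff(e) > 0):
            raise ValueError(
                "residual expectancies must be positive and non-increasing"
            )
        a.setflags(write=False)
        e.setflags(write=False)
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "expectancies", e)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "residual_expectancy"} <= set(df.columns):
            raise ValueError(
                "life-table CSV needs columns 'age' and 'residual_expectancy'"
            )
        return cls(df["age"].to_numpy(), df["residual_expectancy"].to_numpy())

    def residual_expectancy(self, age: float) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise ValueError(
                f"age {age} outside life-table range "
                f"[{self.ages[0]}, {self.ages[-1]}] (no extrapolation)"
            )
        return float(np.interp(age, self.ages, self.expectancies))


@dataclass(frozen=True)
class BurdenResult:
    """Per-year YLD/YLL series plus totals; DALY = YLD + YLL."""

    yld_by_cycle: np.ndarray
    yll_by_cycle: np.ndarray

    @property
    def total_yld(self) -> float:
        return float(self.yld_by_cycle.sum())

    @property
    def total_yll(self) -> float:
        return float(self.yll_by_cycle.sum())

    @property
    def total_daly(self) -> float:
        return self.total_yld + self.total_yll

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(1, len(self.yld_by_cycle) + 1),
                "yld": self.yld_by_cycle,
                "yll": self.yll_by_cycle,
                "daly": self.yld_by_cycle + self.yll_by_cycle,
            }
        )

    def __add__(self, other: "BurdenResult") -> "BurdenResult":
        return BurdenResult(
            self.yld_by_cycle + other.yld_by_cycle,
            self.yll_by_cycle + other.yll_by_cycle,
        )

    def scaled(self, factor: float) -> "BurdenResult":
        return BurdenResult(self.yld_by_cycle * factor, self.yll_by_cycle * factor)


def murray_burden(D: float, alpha: float, L: float, params: DalyParams) -> float:
    """Age-weighted, discounted burden of ``L`` years at weight ``D``.

    Closed form of the burden integral (see module docstring) for a
    condition of disability weight ``D`` starting at age ``alpha`` and
    lasting ``L`` years::

        -(D C e^{-beta alpha} / r^2) * ( e^{-r L} [1 + r (L + alpha)]
                                         - [1 + r alpha] ),   r = beta + gamma

    Requires ``beta + gamma > 0``; the unweighted-undiscounted limit is
    a different formula and is out of scope here.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError("disability weight D must lie in [0, 1]")
    if alpha < 0 or L < 0:
        raise ValueError("alpha and L must be non-negative")
    r = params.beta + params.gamma
    if r <= 0:
        raise ValueError(
            "beta + gamma must be positive; the unweighted, undiscounted "
            "variant is not provided"
        )
    braced = np.exp(-r * L) * (1.0 + r * (L + alpha)) - (1.0 + r * alpha)
    return float(-(D * params.C * np.exp(-params.beta * alpha) / r**2) * braced)


def yld_from_trajectory(traj: CohortTrajectory, params: DalyParams) -> BurdenResult:
    """Years lived with disability, one term per live state and year.

    Year j (1-based) contributes, for every state, its end-of-cycle-j
    occupancy times the burden of one year at weight ``D_state`` started
    at age ``start_age + j - 1`` (the age at the start of that year).
    Zero-weight states contribute nothing; a state without a configured
    weight raises.
    """
    n = traj.n_cycles
    yld = np.zeros(n)
    for s in HealthState:
        if s is HealthState.DEAD:
            continue
        w = params.weight(s)
        if w == 0.0:
            continue
        for k in range(n):  # year k+1, onset age start_age + k
            occ = traj.occupancy[k + 1, s]
            if occ:
                yld[k] += occ * murray_burden(w, traj.start_age + k, 1.0, params)
    return BurdenResult(yld_by_cycle=yld, yll_by_cycle=np.zeros(n))


def yll_from_deaths(
    deaths: np.ndarray,
    start_age: float,
    params: DalyParams,
    table: LifeTable,
) -> BurdenResult:
    """Years of life lost from a per-cycle incident-death series.

    Element k of ``deaths`` (deaths during follow-up year k+1, from
    :func:`~cervecon.markov.incident_deaths`) is assigned age at death
    ``start_age + k`` and loses the residual life expectancy at that
    age, weighted and discounted from that age.
    """
    deaths = np.asarray(deaths, dtype=float)
    yll = np.zeros(deaths.size)
    for k, d in enumerate(deaths):
        if d:
            age = start_age + k
            L = table.residual_expectancy(age)
            yll[k] = d * murray_burden(1.0, age, L, params)
    return BurdenResult(yld_by_cycle=np.zeros(deaths.size), yll_by_cycle=yll)


def averted_dalys(
    case_mix: Mapping,
    P: TransitionMatrix,
    params: DalyParams,
    table: LifeTable,
    start_age: float,
    n_cycles: int = 15,
) -> BurdenResult:
    """Counterfactual burden of confirmed cases left untreated.

    Each confirmed case enters the natural-history model in its
    diagnosed state and runs untreated for ``n_cycles``; the summed
    YLD + YLL is the burden screening-plus-treatment is credited with
    averting (treated cases are assigned zero residual burden).
    """
    total = BurdenResult(np.zeros(n_cycles), np.zeros(n_cycles))
    for grade, count in case_mix.items():
        s = as_state(grade)
        if s is HealthState.DEAD:
            raise ValueError("a confirmed case cannot be diagnosed in state DEAD")
        if count < 0:
            raise ValueError("case counts must be non-negative")
        if count == 0:
            continue
        dist0 = np.zeros(len(HealthState))
        dist0[s] = 1.0
        traj = simulate(dist0, P, n_cycles=n_cycles, start_age=start_age)
        per_case = yld_from_trajectory(traj, params) + yll_from_deaths(
            incident_deaths(traj), start_age, params, table
        )
        total = total + per_case.scaled(count)
    return total
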