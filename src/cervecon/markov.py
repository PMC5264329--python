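"""Markov cohort simulation of untreated cervical-disease natural history.

A cohort (an expected-count occupancy vector over the seven health
states) is advanced through annual cycles by right-multiplication with a
validated row-stochastic transition matrix.  The trajectory records
end-of-cycle occupancy; no half-cycle correction is applied (switchable
via ``half_cycle`` should a user want the mid-cycle convention).

Person-time and incident deaths derived here feed the DALY computation:
``incident_deaths`` gives the per-cycle increments of the absorbing DEAD
state, ``person_years_by_state`` the per-cycle live-state occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import HealthState, N_STATES, STATE_NAMES

__all__ = [
    "MatrixValidationError",
    "TransitionMatrix",
    "CohortTrajectory",
    "distribution",
    "step",
    "simulate",
    "incident_deaths",
    "person_years_by_state",
]

#: row-sum slack accepted on input (absorbs 3-decimal rounding of entries)
ROW_SUM_TOL = 1e-6


class MatrixValidationError(ValueError):
    """Raised when a candidate transition matrix violates an invariant."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Validated 7x7 annual transition-probability matrix.

    Rows are origin states, columns destination states, in
    :class:`~cervecon.states.HealthState` order.  Construct through
    :meth:`from_array` or :meth:`from_csv`; direct construction skips
    validation only if ``probs`` already passed it.
    """

    probs: np.ndarray = field(repr=False)
    cycle_years: float = 1.0

    @classmethod
    def from_array(cls, raw, *, renormalize: bool = False) -> "TransitionMatrix":
        """Validate a 7x7 grid of probabilities and wrap it.

        Raises :class:`MatrixValidationError` naming the offending row
        for a row-sum violation beyond ``ROW_SUM_TOL``, any negative or
        >1 entry, a non-absorbing DEAD row, or a CANCER row with mass on
        a regressed state.  ``renormalize=True`` rescales rows whose sum
        is within tolerance to sum exactly to 1.
        """
        P = np.asarray(raw, dtype=float)
        if P.shape != (N_STATES, N_STATES):
            raise MatrixValidationError(
                f"expected a {N_STATES}x{N_STATES} matrix, got shape {P.shape}"
            )
        if np.any(~np.isfinite(P)):
            raise MatrixValidationError("matrix contains non-finite entries")
        bad = np.argwhere((P < 0) | (P > 1))
        if bad.size:
            i, j = bad[0]
            raise MatrixValidationError(
                f"entry ({STATE_NAMES[i]}, {STATE_NAMES[j]}) = {P[i, j]} "
                "outside [0, 1]"
            )
        sums = P.sum(axis=1)
        off = np.argwhere(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if off.size:
            i = int(off[0][0])
            raise MatrixValidationError(
                f"row {i + 1} ({STATE_NAMES[i]}) sums to {sums[i]:.6f}, not 1"
            )
        dead = HealthState.DEAD
        unit = np.zeros(N_STATES)
        unit[dead] = 1.0
        if not np.array_equal(P[dead] != 0, unit != 0) or P[dead, dead] != 1.0:
            raise MatrixValidationError(
                "DEAD row must be absorbing (unit mass on DEAD)"
            )
        cancer = HealthState.CANCER
        allowed = np.zeros(N_STATES, dtype=bool)
        allowed[[cancer, dead]] = True
        if np.any(P[cancer][~allowed] != 0):
            raise MatrixValidationError(
                "CANCER row may only place mass on CANCER and DEAD"
            )
        if renormalize:
            P = P / sums[:, None]
        P = P.copy()
        P.setflags(write=False)
        return cls(probs=P)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TransitionMatrix":
        """Read an 8x8 labelled CSV (header row + state-name column).

        Row and column labels must match the canonical state order
        exactly; a reordered file is rejected rather than silently
        permuted.
        """
        df = pd.read_csv(path, index_col=0)
        labels = list(df.index)
        cols = list(df.columns)
        if labels != list(STATE_NAMES) or cols != list(STATE_NAMES):
            raise MatrixValidationError(
                f"state labels must be {list(STATE_NAMES)} in order; "
                f"got rows={labels}, cols={cols}"
            )
        return cls.from_array(df.to_numpy(), **kwargs)

    def __post_init__(self):
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))

    def power(self, n: int) -> np.ndarray:
        return np.linalg.matrix_power(self.probs, n)

    def __eq__(self, other):
        return (
            isinstance(other, TransitionMatrix)
            and np.array_equal(self.probs, other.probs)
            and self.cycle_years == other.cycle_years
        )


def distribution(counts=None, **by_state) -> np.ndarray:
    """Build an occupancy vector (expected persons per state).

    Either pass a length-7 sequence, or keyword counts by state name,
    e.g. ``distribution(UNTESTED=1000)``.
    """
    if counts is not None:
        v = np.asarray(counts, dtype=float)
        if v.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} occupancies, got {v.shape}")
    else:
        v = np.zeros(N_STATES)
        for name, c in by_state.items():
            v[HealthState[name]] = c
    if np.any(v < 0):
        raise ValueError("occupancies must be non-negative")
    return v


@dataclass(frozen=True)
class CohortTrajectory:
    """End-of-cycle occupancy of each state for cycles 0..n_cycles.

    ``occupancy[k, s]`` is the expected number of persons in state ``s``
    at the end of cycle ``k`` (cycle 0 = the starting distribution).
    """

    occupancy: np.ndarray  # shape (n_cycles + 1, 7)
    start_age: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, HealthState.DEAD]

    @property
    def live_mass(self) -> np.ndarray:
        return self.occupancy.sum(axis=1) - self.dead

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_NAMES)
        df.insert(0, "cycle", np.arange(self.n_cycles + 1))
        df.insert(1, "age", self.start_age + np.arange(self.n_cycles + 1))
        return df


def step(dist: np.ndarray, P: TransitionMatrix) -> np.ndarray:
    """One annual cycle: row-vector times matrix; conserves total mass."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_STATES,):
        raise ValueError(f"occupancy vector must have length {N_STATES}")
    return dist @ P.probs


def simulate(
    dist0,
    P: TransitionMatrix,
    n_cycles: int = 15,
    start_age: float = 45.0,
) -> CohortTrajectory:
    """Advance a cohort ``n_cycles`` annual cycles from ``dist0``.

    Distribution at cycle k equals ``dist0 @ P**k``; computed by
    repeated vector-matrix products (numerically identical to the
    matrix-power route for the horizons used here).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    dist0 = np.asarray(dist0, dtype=float)
    occ = np.empty((n_cycles + 1, N_STATES))
    occ[0] = dist0
    for k in range(n_cycles):
        occ[k + 1] = occ[k] @ P.probs
    occ.setflags(write=False)
    return CohortTrajectory(occupancy=occ, start_age=float(start_age))


def incident_deaths(traj: CohortTrajectory) -> np.ndarray:
    """Per-cycle new deaths: element k = DEAD(k+1) - DEAD(k), k = 0..N-1.

    Element k is the expected number of deaths occurring during year
    k+1 of follow-up.  Non-negative (up to round-off) because DEAD is
    absorbing; the series sums to final minus initial DEAD occupancy.
    """
    return np.diff(traj.dead)


def person_years_by_state(traj: CohortTrajectory) -> pd.DataFrame:
    """Live-state person-years per follow-up year (end-of-cycle counting).

    Row k (year k+1 of follow-up) holds the end-of-cycle-(k+1) occupancy
    of each live state; the grand total equals the summed live mass over
    cycles 1..N.
    """
    live = [s.name for s in HealthState if s is not HealthState.DEAD]
    df = pd.DataFrame(
        traj.occupancy[1:, : HealthState.DEAD], columns=live
    )
    df.insert(0, "year", np.arange(1, traj.n_cycles + 1))
    return df
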