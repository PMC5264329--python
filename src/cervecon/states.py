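"""Health states of the cervical-disease natural-history model.

The model tracks a cohort of women through seven mutually exclusive
states: disease-free (``UNTESTED``), transient HPV infection, the three
grades of cervical intraepithelial neoplasia (CIN 1-3), invasive cancer
and death.  The integer value of each member is its row/column index in
the annual transition-probability matrix, so the enum order *is* the
matrix order.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """Markov health state; the integer value indexes the matrix row."""

    UNTESTED = 0
    HPV_INFECTION = 1
    CIN1 = 2
    CIN2 = 3
    CIN3 = 4
    CANCER = 5
    DEAD = 6

    @property
    def is_absorbing(self) -> bool:
        return self is HealthState.DEAD

    @property
    def is_non_regressing(self) -> bool:
        """CANCER and DEAD never transition back to a milder state."""
        return self in (HealthState.CANCER, HealthState.DEAD)


#: canonical state order (matrix rows/columns)
STATE_ORDER: tuple[HealthState, ...] = tuple(HealthState)
STATE_NAMES: tuple[str, ...] = tuple(s.name for s in HealthState)
N_STATES: int = len(HealthState)

#: live (non-absorbing) states, in matrix order
LIVE_STATES: tuple[HealthState, ...] = tuple(
    s for s in HealthState if s is not HealthState.DEAD
)

#: pathology grades a confirmed screening positive can carry
GRADES: tuple[HealthState, ...] = (
    HealthState.CIN1,
    HealthState.CIN2,
    HealthState.CIN3,
    HealthState.CANCER,
)

#: grades managed surgically (CIN1 gets follow-up only)
TREATED_GRADES: tuple[HealthState, ...] = (
    HealthState.CIN2,
    HealthState.CIN3,
    HealthState.CANCER,
)


def as_state(value: "HealthState | str | int") -> HealthState:
    """Coerce a name, index or member to a :class:`HealthState`."""
    if isinstance(value, HealthState):
        return value
    if isinstance(value, str):
        try:
            return HealthState[value]
        except KeyError:
            raise ValueError(f"unknown health state {value!r}") from None
    return HealthState(value)
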