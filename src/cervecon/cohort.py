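"""Synthetic three-arm screening-trial cohort generator.

Emulates the structure of a cluster-sampled cervical-cancer screening
trial: ~3,086 women aged 35-65 recruited, ~97.9% participating, each
participant randomised to one of three arms (VIA/VILI, liquid-based
cytology, HPV test).  Screen positives are referred to colposcopy
(directly, or after triage in the HPV arm, summarised by an aggregate
referral fraction), some are lost to follow-up, and attendees receive a
pathology grade.

Two modes:

* ``deterministic`` — expected counts rounded at every stage and grades
  apportioned by largest remainder, reproducing the calibration's exact
  realized counts (used for table reproduction);
* ``stochastic`` — per-stage binomial/multinomial draws (used to stress
  the downstream pipeline).

Ages are uniform on [35, 65]; the cluster structure of the original
sampling is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .costs import CaseMix
from .states import GRADES, as_state

__all__ = ["ArmSpec", "generate", "aggregate", "arm_specs_from_yaml"]

ARM_NAMES = ("VIA_VILI", "TCT", "HPV")


@dataclass(frozen=True)
class ArmSpec:
    """Calibrated per-arm screening probabilities.

    ``triage`` is ``"direct-colposcopy"`` when initial positives go
    straight to colposcopy and ``"HPV-triage-split"`` when an aggregate
    fraction summarises triage sub-groups.
    """

    name: str
    arm_size: int
    p_initial_positive: float
    p_referred_given_positive: float
    p_attend_given_referred: float
    p_confirmed_given_colposcopy: float
    grade_distribution: Mapping = field(default_factory=dict)
    triage: str = "direct-colposcopy"

    def __post_init__(self):
        for f in (
            "p_initial_positive",
            "p_referred_given_positive",
            "p_attend_given_referred",
            "p_confirmed_given_colposcopy",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1], got {v}")
        gd = {as_state(g): float(p) for g, p in self.grade_distribution.items()}
        for g in gd:
            if g not in GRADES:
                raise ValueError(f"{g.name} is not a pathology grade")
        if gd and abs(sum(gd.values()) - 1.0) > 1e-9:
            raise ValueError("grade_distribution must sum to 1")
        object.__setattr__(self, "grade_distribution", gd)


def arm_specs_from_yaml(path) -> tuple[list[ArmSpec], dict]:
    """Build calibrated ArmSpecs from a study aggregates file.

    Returns the specs plus the trial-level parameters (n_recruited,
    participation, ...).  Probabilities are the ratios of the realized
    counts, so deterministic generation round-trips them exactly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for a in raw["arms"]:
        mix = {as_state(g): int(n) for g, n in a["case_mix"].items()}
        n_conf = sum(mix.values())
        n_attend = a["n_referred"] - a["n_lost_followup"]
        specs.append(
            ArmSpec(
                name=a["name"],
                arm_size=a["n_screened"],
                p_initial_positive=a["n_initial_positive"] / a["n_screened"],
                p_referred_given_positive=a["n_referred"] / a["n_initial_positive"],
                p_attend_given_referred=n_attend / a["n_referred"],
                p_confirmed_given_colposcopy=n_conf / n_attend if n_attend else 0.0,
                grade_distribution=(
                    {g: n / n_conf for g, n in mix.items()} if n_conf else {}
                ),
                triage=(
                    "HPV-triage-split" if a["name"] == "HPV" else "direct-colposcopy"
                ),
            )
        )
    meta = {k: v for k, v in raw.items() if k != "arms"}
    return specs, meta


def _largest_remainder(total: int, probs: dict) -> dict:
    """Apportion ``total`` over categories proportionally to ``probs``."""
    if not probs or total == 0:
        return {}
    keys = list(probs)
    raw = np.array([probs[k] * total for k in keys])
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return {k: int(n) for k, n in zip(keys, base) if n}


def generate(
    seed: int,
    specs: Sequence[ArmSpec],
    n_total: int = 3086,
    participation: float = 0.979,
    mode: str = "deterministic",
) -> pd.DataFrame:
    """Generate one synthetic per-woman screening dataset.

    Returns a DataFrame with one row per recruited woman: ``woman_id``,
    ``age``, ``arm`` (empty for non-participants), ``participated``,
    ``initial_result`` ("positive"/"negative"), ``referred``,
    ``attended_colposcopy`` and ``pathology`` (grade name or "").
    Reproducible for a fixed seed; arm sizes must fit within
    ``n_total * participation``.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0.0 <= participation <= 1.0:
        raise ValueError("participation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_participants = int(round(n_total * participation))
    sizes = [s.arm_size for s in specs]
    if sum(sizes) > n_participants:
        raise ValueError(
            f"arm sizes {sizes} exceed participants "
            f"{n_participants} (= round({n_total} x {participation}))"
        )

    ages = rng.uniform(35.0, 65.0, size=n_total)
    rows = []
    woman = 0
    for spec in specs:
        if mode == "deterministic":
            n_pos = int(round(spec.arm_size * spec.p_initial_positive))
            n_ref = int(round(n_pos * spec.p_referred_given_positive))
            n_att = int(round(n_ref * spec.p_attend_given_referred))
            n_conf = int(round(n_att * spec.p_confirmed_given_colposcopy))
            grades = _largest_remainder(n_conf, dict(spec.grade_distribution))
        else:
            n_pos = int(rng.binomial(spec.arm_size, spec.p_initial_positive))
            n_ref = int(rng.binomial(n_pos, spec.p_referred_given_positive))
            n_att = int(rng.binomial(n_ref, spec.p_attend_given_referred))
            n_conf = int(rng.binomial(n_att, spec.p_confirmed_given_colposcopy))
            gd = dict(spec.grade_distribution)
            if gd and n_conf:
                keys = list(gd)
                draws = rng.multinomial(n_conf, [gd[k] for k in keys])
                grades = {k: int(n) for k, n in zip(keys, draws) if n}
            else:
                grades = {}
        grade_seq: list[str] = []
        for g, n in grades.items():
            grade_seq.extend([g.name] * n)
        for i in range(spec.arm_size):
            positive = i < n_pos
            referred = positive and i < n_ref
            attended = referred and i < n_att
            pathology = ""
            if attended and i < n_conf and i < len(grade_seq):
                pathology = grade_seq[i]
            rows.append(
                {
                    "woman_id": woman,
                    "age": ages[woman],
                    "arm": spec.name,
                    "participated": True,
                    "initial_result": "positive" if positive else "negative",
                    "referred": referred,
                    "attended_colposcopy": attended,
                    "pathology": pathology,
                }
            )
            woman += 1
    for _ in range(n_total - woman):
        rows.append(
            {
                "woman_id": woman,
                "age": ages[woman],
                "arm": "",
                "participated": False,
                "initial_result": "",
                "referred": False,
                "attended_colposcopy": False,
                "pathology": "",
            }
        )
        woman += 1
    return pd.DataFrame(rows)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Per-arm counts feeding the costing and effectiveness stages.

    Validates the record invariants (pathology only with colposcopy
    attendance, referral only with a positive initial screen) and
    returns one row per arm: n_screened, n_initial_positive,
    n_referred, n_attended, n_confirmed and the grade case mix.
    """
    required = {
        "arm", "participated", "initial_result", "referred",
        "attended_colposcopy", "pathology",
    }
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    scr = records[records["participated"].astype(bool)]
    bad = scr[(scr["pathology"] != "") & ~scr["attended_colposcopy"]]
    if len(bad):
        raise ValueError("pathology recorded without colposcopy attendance")
    bad = scr[scr["referred"] & (scr["initial_result"] != "positive")]
    if len(bad):
        raise ValueError("referral recorded without a positive initial screen")

    out = []
    for arm, g in scr.groupby("arm", sort=False):
        mix_counts = (
            g.loc[g["pathology"] != "", "pathology"].value_counts().to_dict()
        )
        out.append(
            {
                "arm": arm,
                "n_screened": int(len(g)),
                "n_initial_positive": int((g["initial_result"] == "positive").sum()),
                "n_referred": int(g["referred"].sum()),
                "n_attended": int(g["attended_colposcopy"].sum()),
                "n_confirmed": int(sum(mix_counts.values())),
                "case_mix": CaseMix(mix_counts),
            }
        )
    return pd.DataFrame(out)
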