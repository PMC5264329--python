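"""Bundled study-calibration inputs.

All numeric inputs of the evaluation — the annual transition matrix,
unit costs, per-arm screening cost components, DALY constants, the
female residual-life-expectancy table and the per-arm trial aggregates —
ship as plain data files under ``cervecon/data`` and load here.  The
``study`` profile reproduces the three-arm rural screening evaluation
the package is calibrated to; every file is replaceable by a
user-supplied path of the same layout.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import arm_specs_from_yaml
from .costs import UnitCostSchedule, load_screening_components
from .daly import DalyParams, LifeTable
from .markov import TransitionMatrix

__all__ = [
    "data_path",
    "load_transition_matrix",
    "load_life_table",
    "load_unit_costs",
    "load_daly_params",
    "load_screening_table",
    "load_arm_aggregates",
    "load_arm_specs",
]


def data_path(name: str):
    """Filesystem path of a bundled data file."""
    return resources.files("cervecon").joinpath("data", name)


def load_transition_matrix() -> TransitionMatrix:
    with resources.as_file(data_path("transition_matrix.csv")) as p:
        return TransitionMatrix.from_csv(p)


def load_life_table() -> LifeTable:
    with resources.as_file(data_path("life_table_female.csv")) as p:
        return LifeTable.from_csv(p)


def load_unit_costs() -> UnitCostSchedule:
    with resources.as_file(data_path("unit_costs.yaml")) as p:
        return UnitCostSchedule.from_yaml(p)


def load_daly_params() -> DalyParams:
    with resources.as_file(data_path("daly_params.yaml")) as p:
        return DalyParams.from_yaml(p)


def load_screening_table() -> pd.DataFrame:
    with resources.as_file(data_path("screening_components.csv")) as p:
        return load_screening_components(p)


def load_arm_aggregates() -> dict:
    """Raw study aggregates (arm counts, case mixes, trial metadata)."""
    import yaml

    with resources.as_file(data_path("arms.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def load_arm_specs():
    """Calibrated synthetic-cohort ArmSpecs plus trial metadata."""
    with resources.as_file(data_path("arms.yaml")) as p:
        return arm_specs_from_yaml(p)
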