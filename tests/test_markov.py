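"""Markov cohort simulation: validation, stepping, derived series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervecon import (
    HealthState,
    MatrixValidationError,
    TransitionMatrix,
    distribution,
    incident_deaths,
    person_years_by_state,
    simulate,
    step,
)
from .conftest import STUDY_MATRIX


class TestValidation:
    def test_study_matrix_accepted_rows_sum_to_one(self, study_matrix):
        assert np.allclose(study_matrix.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_identity_matrix_accepted(self):
        TransitionMatrix.from_array(np.eye(7))

    def test_row_sum_violation_names_the_row(self):
        bad = STUDY_MATRIX.copy()
        bad[0, 0] = 0.9  # row sum 1.024
        with pytest.raises(MatrixValidationError, match="row 1"):
            TransitionMatrix.from_array(bad)

    def test_negative_entry_rejected(self):
        bad = STUDY_MATRIX.copy()
        bad[1, 0] -= 0.002
        bad[1, 1] += 0.002
        bad[1, 0] = -0.001  # keep row sum ~1 but negative entry
        bad[1, 1] = 1.0 - bad[1, 0] - bad[1, 2:].sum()
        with pytest.raises(MatrixValidationError, match="outside"):
            TransitionMatrix.from_array(bad)

    def test_non_absorbing_dead_row_rejected(self):
        bad = STUDY_MATRIX.copy()
        bad[6] = [0.001, 0, 0, 0, 0, 0, 0.999]
        with pytest.raises(MatrixValidationError, match="DEAD"):
            TransitionMatrix.from_array(bad)

    def test_regressing_cancer_row_rejected(self):
        bad = STUDY_MATRIX.copy()
        bad[5] = [0.01, 0, 0, 0, 0, 0.751, 0.239]
        with pytest.raises(MatrixValidationError, match="CANCER"):
            TransitionMatrix.from_array(bad)

    def test_csv_round_trip_matches_printed_matrix(self, bundled_matrix, study_matrix):
        assert np.array_equal(bundled_matrix.probs, study_matrix.probs)

    def test_reordered_csv_labels_rejected(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            STUDY_MATRIX,
            index=[s.name for s in HealthState],
            columns=[s.name for s in HealthState],
        )
        shuffled = df.iloc[::-1]
        p = tmp_path / "m.csv"
        shuffled.to_csv(p, index_label="state")
        with pytest.raises(MatrixValidationError, match="order"):
            TransitionMatrix.from_csv(p)


class TestStep:
    def test_one_step_from_1000_untested(self, study_matrix):
        d1 = step(distribution(UNTESTED=1000), study_matrix)
        assert d1 == pytest.approx([876.0, 123.0, 0, 0, 0, 0, 1.0], abs=1e-9)

    def test_dead_cohort_is_fixed(self, study_matrix):
        d = distribution(DEAD=100)
        assert step(d, study_matrix) == pytest.approx(d)

    def test_cancer_cohort_splits_geometrically(self, study_matrix):
        d1 = step(distribution(CANCER=50), study_matrix)
        assert d1 == pytest.approx([0, 0, 0, 0, 0, 38.05, 11.95])

    def test_dimension_mismatch_rejected(self, study_matrix):
        with pytest.raises(ValueError):
            step(np.ones(6), study_matrix)


class TestSimulate:
    def test_matches_matrix_power_oracle_from_cin2(self, study_matrix):
        d0 = distribution(CIN2=1)
        traj = simulate(d0, study_matrix, n_cycles=2)
        # independent oracle: explicit matrix squaring
        P2 = STUDY_MATRIX @ STUDY_MATRIX
        assert traj.occupancy[2] == pytest.approx(P2[HealthState.CIN2], abs=1e-12)

    def test_matches_repeated_multiplication_for_all_horizons(self, study_matrix):
        rng = np.random.default_rng(7)
        d0 = rng.uniform(0, 100, size=7)
        traj = simulate(d0, study_matrix, n_cycles=15)
        expected = d0.copy()
        for k in range(1, 16):
            expected = expected @ STUDY_MATRIX
            assert traj.occupancy[k] == pytest.approx(expected, abs=1e-12)

    def test_identity_matrix_freezes_cohort(self):
        P = TransitionMatrix.from_array(np.eye(7))
        d0 = distribution(CIN1=3, CANCER=2)
        traj = simulate(d0, P, n_cycles=5)
        assert np.all(traj.occupancy == d0)

    def test_dead_start_stays_dead(self, study_matrix):
        traj = simulate(distribution(DEAD=1), study_matrix, n_cycles=15)
        assert np.all(traj.dead == 1.0)
        assert np.all(traj.live_mass == pytest.approx(0.0, abs=1e-15))

    def test_rejects_zero_cycles(self, study_matrix):
        with pytest.raises(ValueError):
            simulate(distribution(UNTESTED=1), study_matrix, n_cycles=0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        counts=st.lists(
            st.floats(0, 1e4, allow_nan=False, allow_infinity=False),
            min_size=7,
            max_size=7,
        ),
        n=st.integers(1, 15),
    )
    def test_mass_conservation_and_monotone_mortality(self, counts, n):
        P = TransitionMatrix.from_array(STUDY_MATRIX)
        d0 = np.array(counts)
        traj = simulate(d0, P, n_cycles=n)
        total = d0.sum()
        masses = traj.occupancy.sum(axis=1)
        assert masses == pytest.approx(total, rel=1e-9, abs=1e-9)
        assert np.all(np.diff(traj.dead) >= -1e-9 * max(total, 1.0))

    def test_all_mass_eventually_absorbs_in_dead(self, study_matrix):
        # dominant live-block eigenvalue is ~0.9972, so live mass decays
        # like 0.9972^n: below 1e-3 per starting person by n = 3000
        d = distribution(UNTESTED=1.0)
        final = d @ study_matrix.power(3000)
        assert final.sum() == pytest.approx(1.0, rel=1e-9)
        assert 1.0 - final[HealthState.DEAD] < 1e-3


class TestDerivedSeries:
    def test_first_cycle_deaths_from_untested(self, study_matrix):
        traj = simulate(distribution(UNTESTED=1000), study_matrix, n_cycles=1)
        assert incident_deaths(traj) == pytest.approx([1.0])

    def test_all_dead_trajectory_has_no_incident_deaths(self, study_matrix):
        traj = simulate(distribution(DEAD=5), study_matrix, n_cycles=10)
        assert incident_deaths(traj) == pytest.approx(np.zeros(10), abs=1e-12)

    def test_cancer_cohort_deaths_are_geometric(self, study_matrix):
        traj = simulate(distribution(CANCER=1), study_matrix, n_cycles=15)
        deaths = incident_deaths(traj)
        expected = 0.239 * 0.761 ** np.arange(15)  # closed-form series
        assert deaths == pytest.approx(expected, abs=1e-12)
        assert deaths.sum() == pytest.approx(1 - 0.761**15, abs=1e-12)

    def test_deaths_sum_to_dead_increment(self, study_matrix):
        traj = simulate(distribution(CIN3=10, HPV_INFECTION=5), study_matrix, 15)
        assert incident_deaths(traj).sum() == pytest.approx(
            traj.dead[-1] - traj.dead[0]
        )

    def test_person_years_zero_for_dead_cohort(self, study_matrix):
        traj = simulate(distribution(DEAD=1), study_matrix, n_cycles=4)
        py = person_years_by_state(traj)
        assert py.drop(columns="year").to_numpy().sum() == pytest.approx(0.0)

    def test_person_years_first_year_from_untested(self, study_matrix):
        traj = simulate(distribution(UNTESTED=1000), study_matrix, n_cycles=1)
        py = person_years_by_state(traj).drop(columns="year")
        assert py.iloc[0].to_numpy() == pytest.approx([876.0, 123.0, 0, 0, 0, 0])

    def test_person_years_match_explicit_row_restriction(self, study_matrix):
        # oracle: rows of P, P^2, P^3 restricted to the CIN3 origin row
        traj = simulate(distribution(CIN3=1), study_matrix, n_cycles=3)
        py = person_years_by_state(traj).drop(columns="year").to_numpy()
        for k in (1, 2, 3):
            row = np.linalg.matrix_power(STUDY_MATRIX, k)[HealthState.CIN3]
            assert py[k - 1] == pytest.approx(row[:6], abs=1e-12)
        live = traj.live_mass[1:]
        assert py.sum() == pytest.approx(live.sum(), abs=1e-12)
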