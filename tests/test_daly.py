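"""DALY metrics: closed form vs quadrature, cohort YLD/YLL accumulation."""

import numpy as np
import pytest
from scipy.integrate import quad

from cervecon import (
    BurdenResult,
    CaseMix,
    DalyParams,
    HealthState,
    LifeTable,
    TransitionMatrix,
    averted_dalys,
    distribution,
    incident_deaths,
    murray_burden,
    simulate,
    yld_from_trajectory,
    yll_from_deaths,
)
from cervecon.markov import CohortTrajectory


def integral_oracle(D, alpha, L, params):
    """Adaptive quadrature of the age-weighted discounted burden integral."""
    f = lambda x: (
        D
        * params.C
        * (alpha + x)
        * np.exp(-params.beta * (alpha + x))
        * np.exp(-params.gamma * x)
    )
    val, err = quad(f, 0, L, limit=200)
    return val


class TestMurrayBurden:
    def test_zero_duration_is_zero(self, daly_params):
        assert murray_burden(1.0, 40.0, 0.0, daly_params) == pytest.approx(0.0)

    def test_zero_weight_is_zero(self, daly_params):
        assert murray_burden(0.0, 25.0, 30.0, daly_params) == 0.0

    @pytest.mark.parametrize("alpha", [20.0, 35.0, 50.0, 65.0])
    @pytest.mark.parametrize("L", [1.0, 5.0, 10.0, 30.0])
    @pytest.mark.parametrize("D", [0.1238, 0.1941, 0.307, 1.0])
    def test_closed_form_equals_quadrature(self, D, alpha, L, daly_params):
        expected = integral_oracle(D, alpha, L, daly_params)
        got = murray_burden(D, alpha, L, daly_params)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_monotone_increasing_in_duration_and_weight(self, daly_params):
        b = lambda D, L: murray_burden(D, 35.0, L, daly_params)
        durations = [1, 2, 5, 10, 20, 40]
        vals = [b(0.5, L) for L in durations]
        assert all(x < y for x, y in zip(vals, vals[1:]))
        weights = [0.1, 0.3, 0.6, 1.0]
        vals = [b(D, 10.0) for D in weights]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_strictly_decreasing_in_discount_rate(self):
        gammas = [0.0, 0.01, 0.03, 0.05, 0.10]
        vals = [
            murray_burden(1.0, 35.0, 10.0, DalyParams(gamma=g)) for g in gammas
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_degenerate_discount_and_ageweight_rejected(self):
        params = DalyParams(gamma=0.0, beta=0.0)
        with pytest.raises(ValueError, match="beta \\+ gamma"):
            murray_burden(1.0, 35.0, 10.0, params)


class TestParamsAndLifeTable:
    def test_weight_conventions_enforced(self):
        with pytest.raises(ValueError):
            DalyParams(disability_weights={**dict.fromkeys(HealthState, 0.0),
                                           HealthState.DEAD: 0.5})
        with pytest.raises(ValueError):
            DalyParams(disability_weights={HealthState.CIN1: 0.2,
                                           HealthState.DEAD: 1.0})

    def test_life_table_interpolates_linearly(self, life_table):
        e45 = life_table.residual_expectancy(45)
        e50 = life_table.residual_expectancy(50)
        mid = life_table.residual_expectancy(47.5)
        assert mid == pytest.approx((e45 + e50) / 2)

    def test_life_table_refuses_extrapolation(self, life_table):
        with pytest.raises(ValueError, match="outside"):
            life_table.residual_expectancy(130)

    def test_malformed_life_table_rejected(self):
        with pytest.raises(ValueError):
            LifeTable(ages=[0, 10, 5], expectancies=[80, 70, 75])
        with pytest.raises(ValueError):
            LifeTable(ages=[0, 5, 10], expectancies=[80, 82, 70])


def _constant_trajectory(state, occupancy, n_cycles, start_age):
    """Trajectory whose end-of-cycle occupancy is fixed in one state."""
    occ = np.zeros((n_cycles + 1, 7))
    occ[:, state] = occupancy
    return CohortTrajectory(occupancy=occ, start_age=start_age)


class TestCohortBurden:
    def test_cin1_occupancy_accrues_no_yld(self, daly_params):
        traj = _constant_trajectory(HealthState.CIN1, 1.0, 10, 40.0)
        assert yld_from_trajectory(traj, daly_params).total_yld == 0.0

    def test_one_cin2_year_equals_single_burden_call(self, daly_params):
        a = 42.0
        traj = _constant_trajectory(HealthState.CIN2, 1.0, 1, a)
        res = yld_from_trajectory(traj, daly_params)
        assert res.total_yld == pytest.approx(
            murray_burden(0.1238, a, 1.0, daly_params)
        )

    def test_yld_linear_in_cohort_size(self, study_matrix, daly_params):
        traj1 = simulate(distribution(CIN3=1), study_matrix, 15, start_age=45)
        traj2 = simulate(distribution(CIN3=2), study_matrix, 15, start_age=45)
        y1 = yld_from_trajectory(traj1, daly_params)
        y2 = yld_from_trajectory(traj2, daly_params)
        assert y2.yld_by_cycle == pytest.approx(2 * y1.yld_by_cycle)

    def test_missing_weight_raises(self, study_matrix):
        weights = {s: 0.0 for s in HealthState}
        weights[HealthState.DEAD] = 1.0
        weights[HealthState.CIN3] = 0.1941
        del weights[HealthState.CIN2]
        params = DalyParams(disability_weights=weights)
        traj = simulate(distribution(CIN2=1), study_matrix, 5, start_age=45)
        with pytest.raises(KeyError, match="CIN2"):
            yld_from_trajectory(traj, params)

    def test_no_deaths_no_yll(self, daly_params, life_table):
        res = yll_from_deaths(np.zeros(15), 45.0, daly_params, life_table)
        assert res.total_yll == 0.0

    def test_single_death_is_definitional(self, daly_params, life_table):
        deaths = np.zeros(5)
        deaths[2] = 1.0  # death during year 3, age 47
        res = yll_from_deaths(deaths, 45.0, daly_params, life_table)
        e = life_table.residual_expectancy(47.0)
        assert res.total_yll == pytest.approx(murray_burden(1.0, 47.0, e, daly_params))

    def test_geometric_cancer_deaths_term_by_term(
        self, study_matrix, daly_params, life_table
    ):
        traj = simulate(distribution(CANCER=1), study_matrix, 15, start_age=45)
        res = yll_from_deaths(
            incident_deaths(traj), 45.0, daly_params, life_table
        )
        # hand computation with the quadrature oracle, term by term
        for k in range(15):
            d = 0.239 * 0.761**k
            age = 45.0 + k
            e = life_table.residual_expectancy(age)
            expected = d * integral_oracle(1.0, age, e, daly_params)
            assert res.yll_by_cycle[k] == pytest.approx(expected, rel=1e-6)

    def test_age_outside_table_raises(self, daly_params):
        short = LifeTable(ages=[40, 50], expectancies=[44, 34])
        deaths = np.ones(15)
        with pytest.raises(ValueError, match="outside"):
            yll_from_deaths(deaths, 45.0, daly_params, short)


class TestAvertedDalys:
    def test_empty_case_mix_is_zero(self, study_matrix, daly_params, life_table):
        res = averted_dalys(CaseMix({}), study_matrix, daly_params, life_table, 45)
        assert res.total_daly == 0.0

    def test_absorbing_zero_weight_state_averts_nothing(
        self, daly_params, life_table
    ):
        P = TransitionMatrix.from_array(np.eye(7))  # CIN1 absorbing, weight 0
        res = averted_dalys(
            CaseMix({"CIN1": 1}), P, daly_params, life_table, 45
        )
        assert res.total_daly == 0.0

    def test_dead_diagnosis_rejected(self, study_matrix, daly_params, life_table):
        with pytest.raises(ValueError, match="DEAD"):
            averted_dalys(
                {HealthState.DEAD: 1}, study_matrix, daly_params, life_table, 45
            )

    def test_cancer_case_matches_stepwise_oracle(
        self, study_matrix, daly_params, life_table
    ):
        # spreadsheet-style oracle: survivors 0.761^j accrue weighted YLD,
        # deaths 0.239*0.761^(j-1) accrue YLL at residual expectancy
        res = averted_dalys(
            CaseMix({"CANCER": 1}), study_matrix, daly_params, life_table,
            start_age=45, n_cycles=15,
        )
        expected_yld = sum(
            0.761 ** j * integral_oracle(0.307, 45.0 + j - 1, 1.0, daly_params)
            for j in range(1, 16)
        )
        expected_yll = sum(
            0.239
            * 0.761 ** (j - 1)
            * integral_oracle(
                1.0,
                45.0 + j - 1,
                life_table.residual_expectancy(45.0 + j - 1),
                daly_params,
            )
            for j in range(1, 16)
        )
        assert res.total_yld == pytest.approx(expected_yld, rel=1e-6)
        assert res.total_yll == pytest.approx(expected_yll, rel=1e-6)
        assert res.total_daly == res.total_yld + res.total_yll

    def test_linearity_in_case_counts(self, study_matrix, daly_params, life_table):
        one = averted_dalys(
            CaseMix({"CIN3": 1}), study_matrix, daly_params, life_table, 45
        )
        three = averted_dalys(
            CaseMix({"CIN3": 3}), study_matrix, daly_params, life_table, 45
        )
        assert three.total_daly == pytest.approx(3 * one.total_daly)

    def test_burden_components_nonnegative_and_additive(self):
        a = BurdenResult(np.array([1.0, 2.0]), np.array([0.5, 0.0]))
        b = BurdenResult(np.array([0.0, 1.0]), np.array([1.5, 1.0]))
        c = a + b
        assert c.total_daly == pytest.approx(a.total_daly + b.total_daly)
        assert c.total_daly == c.total_yld + c.total_yll
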