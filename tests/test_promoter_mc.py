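"""Unit and property tests of the five-microstate promoter chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg

from tbpnoise.promoter_mc import (
    MICROSTATES,
    STATE_INDEX,
    ParameterError,
    PromoterParams,
    build_transition_matrix,
    population_noise,
    simulate_population,
    stationary_distribution,
    turnover_rate,
    waiting_time_stats,
)

from conftest import random_params


def stationary_by_eigen(matrix: np.ndarray) -> np.ndarray:
    """Independent oracle: left eigenvector of eigenvalue 1."""
    values, vectors = linalg.eig(matrix.T)
    idx = np.argmin(np.abs(values - 1.0))
    pi = np.real(vectors[:, idx])
    return pi / pi.sum()


class TestBuildTransitionMatrix:
    def test_no_binding_gives_absorbing_free_state(self):
        params = PromoterParams(affinity=0.0, tfiid_recruit=0.0)
        m = build_transition_matrix(params)
        assert m[0].tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_rows_match_direct_substitution(self):
        params = PromoterParams(
            affinity=0.5,
            tfiid_recruit=0.2,
            engage=1.0,
            competition=0.8,
            t_off=0.0,
            residence_m=2,
            residence_s=10,
            residence_d=50,
        )
        m = build_transition_matrix(params)
        np.testing.assert_allclose(m[0], [0.3, 0.5, 0.0, 0.0, 0.2])
        np.testing.assert_allclose(m[1], [0.0, 0.0, 0.8, 0.2, 0.0])
        np.testing.assert_allclose(m[2], [0.5, 0.0, 0.5, 0.0, 0.0])

    def test_unit_mot1p_residence_evicts_in_one_step(self):
        m = build_transition_matrix(PromoterParams(residence_m=1))
        assert m[STATE_INDEX["M"]].tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_forbidden_transitions_are_zero(self):
        m = build_transition_matrix(random_params(np.random.default_rng(3)))
        f, t = STATE_INDEX["f"], STATE_INDEX["T"]
        assert m[f, STATE_INDEX["M"]] == 0.0  # Mot1p needs bound TBP
        assert m[f, STATE_INDEX["S"]] == 0.0  # SAGA engages bound TBP
        assert m[t, STATE_INDEX["D"]] == 0.0  # TFIID arrives holo only

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_rows_sum_to_one_for_random_valid_params(self, seed):
        m = build_transition_matrix(random_params(np.random.default_rng(seed)))
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all() and (m <= 1).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("affinity", -0.1),
            ("affinity", 1.2),
            ("competition", 1.5),
            ("residence_m", 0.5),
            ("burst_s", -1.0),
        ],
    )
    def test_invalid_parameters_name_the_field(self, field, value):
        with pytest.raises(ParameterError, match=field):
            PromoterParams(**{field: value})

    def test_joint_probability_budget_enforced(self):
        with pytest.raises(ParameterError):
            PromoterParams(affinity=0.7, tfiid_recruit=0.5)
        with pytest.raises(ParameterError):
            PromoterParams(engage=0.9, t_off=0.3)


class TestSimulatePopulation:
    def test_deterministic_chain_has_zero_noise(self):
        # f -> D with certainty, D absorbing
        params = PromoterParams(
            affinity=0.0, tfiid_recruit=1.0, residence_d=1e12, burst_d=1.0
        )
        m = build_transition_matrix(params)
        res = simulate_population(m, params, n_cells=20, n_steps=150, seed=4)
        np.testing.assert_array_equal(res.expression, 150.0)
        assert population_noise(res) == 0.0

    def test_never_leaving_f_flags_undefined_cv(self):
        params = PromoterParams(affinity=0.0, tfiid_recruit=0.0)
        m = build_transition_matrix(params)
        res = simulate_population(m, params, n_cells=10, n_steps=50, seed=0)
        assert (res.expression == 0).all()
        with pytest.warns(UserWarning, match="CV undefined"):
            assert np.isnan(population_noise(res))

    def test_seed_determinism_bit_identical(self):
        params = random_params(np.random.default_rng(8))
        m = build_transition_matrix(params)
        a = simulate_population(m, params, n_cells=50, n_steps=100, seed=123)
        b = simulate_population(m, params, n_cells=50, n_steps=100, seed=123)
        np.testing.assert_array_equal(a.histories, b.histories)
        np.testing.assert_array_equal(a.expression, b.expression)

    def test_growing_population_extends_not_reshuffles(self):
        params = random_params(np.random.default_rng(9))
        m = build_transition_matrix(params)
        small = simulate_population(m, params, n_cells=20, n_steps=80, seed=5)
        big = simulate_population(m, params, n_cells=40, n_steps=80, seed=5)
        np.testing.assert_array_equal(big.histories[:20], small.histories)

    def test_expression_equals_burst_weighted_state_counts(self):
        params = random_params(np.random.default_rng(10))
        m = build_transition_matrix(params)
        res = simulate_population(m, params, n_cells=30, n_steps=60, seed=2)
        s = (res.histories == STATE_INDEX["S"]).sum(axis=1)
        d = (res.histories == STATE_INDEX["D"]).sum(axis=1)
        np.testing.assert_allclose(
            res.expression, params.burst_s * s + params.burst_d * d
        )

    def test_non_stochastic_matrix_rejected(self):
        params = PromoterParams()
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_population(bad, params, seed=0)

    def test_long_run_frequencies_match_stationary(self):
        params = PromoterParams()  # TATA-box defaults, fast mixing
        m = build_transition_matrix(params)
        res = simulate_population(m, params, n_cells=1, n_steps=50_000, seed=6)
        freq = np.bincount(res.histories[0], minlength=5) / res.n_steps
        pi = stationary_distribution(m)
        assert np.abs(freq - pi).sum() / 2 < 0.02  # total variation


class TestPopulationNoise:
    def test_constant_expression_zero_cv(self):
        assert population_noise(np.array([5.0, 5, 5, 5])) == 0.0

    def test_two_cell_sample_sd_convention(self):
        # sd([2, 4]) with n-1 = sqrt(2); mean 3
        assert population_noise(np.array([2.0, 4.0])) == pytest.approx(
            np.sqrt(2) / 3, abs=1e-12
        )

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            population_noise(np.array([1.0]))


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        # f <-> D sub-chain: pi = (beta, alpha) / (alpha + beta)
        alpha, beta = 0.3, 0.1
        params = PromoterParams(
            affinity=0.0, tfiid_recruit=alpha, residence_d=1 / beta
        )
        with pytest.warns(UserWarning, match="reducible"):
            pi = stationary_distribution(build_transition_matrix(params))
        np.testing.assert_allclose(
            pi[[0, 4]], [beta / (alpha + beta), alpha / (alpha + beta)],
            atol=1e-9,
        )
        assert pi[[1, 2, 3]].max() < 1e-9

    def test_identity_matrix_flagged_reducible(self):
        with pytest.warns(UserWarning, match="reducible"):
            pi = stationary_distribution(np.eye(5))
        assert pi.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_eigen_oracle_on_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((5, 5))
        m /= m.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            stationary_distribution(m), stationary_by_eigen(m), atol=1e-10
        )


class TestWaitingTimes:
    def _result(self, labels):
        hist = np.array([[STATE_INDEX[s] for s in labels]])
        return type(
            "R", (), {"histories": hist, "n_cells": 1, "n_steps": hist.shape[1]}
        )()

    def test_single_complete_off_run(self):
        stats = waiting_time_stats(self._result("ffDfffS"))
        assert stats.pooled.tolist() == [3]
        assert stats.mean == 3.0

    def test_censored_runs_excluded_by_default(self):
        stats = waiting_time_stats(self._result("ffDfffSff"))
        assert stats.pooled.tolist() == [3]  # leading ff and trailing ff dropped
        with_censored = waiting_time_stats(
            self._result("ffDfffSff"), include_censored=True
        )
        assert sorted(with_censored.pooled.tolist()) == [2, 2, 3]

    def test_all_off_history_flagged_empty(self):
        with pytest.warns(UserWarning, match="no complete Off-runs"):
            stats = waiting_time_stats(self._result("ffTfMfT"))
        assert stats.pooled.size == 0
        assert stats.no_on_state
        assert np.isnan(stats.mean)

    def test_adjacent_on_states_contribute_no_run(self):
        with pytest.warns(UserWarning, match="no complete Off-runs"):
            stats = waiting_time_stats(self._result("SDSD"))
        assert stats.pooled.size == 0


class TestTurnoverRate:
    def _result(self, labels, n_cells=1):
        hist = np.tile(
            np.array([[STATE_INDEX[s] for s in labels]]), (n_cells, 1)
        )
        return type(
            "R", (), {"histories": hist, "n_cells": n_cells, "n_steps": hist.shape[1]}
        )()

    def test_single_binding_locked_in_d(self):
        labels = "D" * 150  # binds at step 1 and never leaves
        assert turnover_rate(self._result(labels)) == pytest.approx(1 / 150)

    def test_alternating_f_t_is_half(self):
        assert turnover_rate(self._result("TfTfTfTf")) == pytest.approx(0.5)

    def test_mot1p_cycling_not_counted_as_new_binding(self):
        # T -> M -> f -> T: only the f -> T entries are new TBP bindings
        assert turnover_rate(self._result("TMfTMf")) == pytest.approx(2 / 6)
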