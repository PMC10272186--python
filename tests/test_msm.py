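"""MSM core: clustering, counting, estimation, timescales, CK, PCCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allostate import (
    DiscreteTrajectory,
    FeatureTrajectory,
    MarkovStateModel,
    assign,
    count_matrix,
    estimate_transition_model,
    fit_kmeans,
    implied_timescales,
    largest_connected_set,
)
from allostate.errors import EstimationError, FeatureMismatchError
from allostate.msm import MacrostateDefinition, _reversible_mle

from ._oracles import reversible_mle_optimizer, stationary_nullspace


# ---------------------------------------------------------------------------
# clustering


class TestKMeans:
    def test_k_equals_distinct_points_gives_zero_wcss(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [3, 3]])
        model = fit_kmeans(pts, 4, seed=0)
        d = np.min(
            np.linalg.norm(pts[:, None, :] - model.centers[None], axis=2), axis=1
        )
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_k1_centre_is_the_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.random((100, 2))
        model = fit_kmeans(pts, 1, seed=0)
        assert np.allclose(model.centers[0], pts.mean(axis=0), atol=1e-10)

    def test_two_blobs_recovered_within_standard_error(self):
        rng = np.random.default_rng(1)
        n = 400
        a = rng.normal([0.0, 0.0], 0.3, (n, 2))
        b = rng.normal([4.0, 4.0], 0.3, (n, 2))
        model = fit_kmeans(np.vstack([a, b]), 2, seed=0)
        centers = model.centers[np.argsort(model.centers[:, 0])]
        se = 0.3 / np.sqrt(n)
        assert np.all(np.abs(centers[0] - a.mean(axis=0)) < 3 * se)
        assert np.all(np.abs(centers[1] - b.mean(axis=0)) < 3 * se)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        pts = rng.random((300, 2))
        m1 = fit_kmeans(pts, 10, seed=5)
        m2 = fit_kmeans(pts, 10, seed=5)
        assert np.array_equal(m1.centers, m2.centers)

    def test_too_few_distinct_rows_rejected(self):
        pts = np.zeros((10, 2))
        with pytest.raises(EstimationError):
            fit_kmeans(pts, 2, seed=0)


class TestAssign:
    model_pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])

    def _model(self):
        return fit_kmeans(self.model_pts, 4, seed=0)

    def test_frame_at_centre_maps_to_it(self):
        model = self._model()
        traj = FeatureTrajectory(model.centers[[2]], model.feature_names)
        assert assign(traj, model).states[0] == 2

    def test_tie_breaks_to_lowest_index(self):
        model = self._model()
        # equidistant from centres at (0,0) and (1,0)
        traj = FeatureTrajectory([[0.5, 0.0]], model.feature_names)
        assert assign(traj, model).states[0] == min(
            np.flatnonzero(
                np.isclose(np.linalg.norm(model.centers - [0.5, 0.0], axis=1),
                           np.min(np.linalg.norm(model.centers - [0.5, 0.0], axis=1)))
            )
        )

    def test_matches_brute_force_argmin(self):
        model = self._model()
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 3, (200, 2))
        got = assign(FeatureTrajectory(X, model.feature_names), model).states
        brute = np.array(
            [np.argmin([np.sum((x - c) ** 2) for c in model.centers]) for x in X]
        )
        assert np.array_equal(got, brute)

    def test_feature_name_mismatch_rejected(self):
        model = self._model()
        traj = FeatureTrajectory([[0.0, 0.0]], ["a", "b"])
        with pytest.raises(FeatureMismatchError):
            assign(traj, model)


# ---------------------------------------------------------------------------
# counting


class TestCountMatrix:
    def test_small_enumerations(self):
        C = count_matrix([np.array([0, 0, 1, 1, 0])], lag=1, n_states=2)
        assert np.array_equal(C, [[1, 1], [1, 1]])
        C2 = count_matrix([np.array([0, 1, 0, 1])], lag=2, n_states=2)
        assert np.array_equal(C2, [[1, 0], [0, 1]])

    def test_matches_independent_pair_counter(self):
        rng = np.random.default_rng(4)
        dtrajs = [rng.integers(0, 5, rng.integers(3, 40)) for _ in range(100)]
        lag = 3
        C = count_matrix(dtrajs, lag, n_states=5)
        expected = np.zeros((5, 5))
        for d in dtrajs:
            for t in range(len(d) - lag):
                expected[d[t], d[t + lag]] += 1
        assert np.array_equal(C, expected)

    def test_trajectories_never_concatenated(self):
        C = count_matrix([np.array([0, 0]), np.array([1, 1])], lag=1, n_states=2)
        assert C[0, 1] == 0 and C[1, 0] == 0

    def test_all_too_short_raises(self):
        with pytest.raises(EstimationError):
            count_matrix([np.array([0, 1])], lag=5, n_states=2)


# ---------------------------------------------------------------------------
# estimation


class TestEstimateTransitionModel:
    def test_two_state_closed_form(self):
        C = np.array([[9.0, 1.0], [2.0, 8.0]])
        res = estimate_transition_model(C, reversible=False)
        assert np.allclose(res.transition_matrix, [[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(res.stationary_distribution, [2 / 3, 1 / 3])

    def test_symmetric_counts_make_both_modes_agree(self):
        C = np.array([[10.0, 4.0, 1.0], [4.0, 20.0, 2.0], [1.0, 2.0, 8.0]])
        rev = estimate_transition_model(C, reversible=True)
        nonrev = estimate_transition_model(C, reversible=False)
        assert np.allclose(rev.transition_matrix, nonrev.transition_matrix, atol=1e-9)

    def test_reversible_satisfies_detailed_balance_and_matches_optimizer(self):
        rng = np.random.default_rng(6)
        C = np.floor(rng.random((4, 4)) * 50) + 1
        res = estimate_transition_model(C, reversible=True)
        T, pi = res.transition_matrix, res.stationary_distribution
        assert np.allclose(pi[:, None] * T, (pi[:, None] * T).T, atol=1e-8)
        T_orc, pi_orc = reversible_mle_optimizer(C)
        assert np.max(np.abs(T - T_orc)) < 1e-6
        assert np.max(np.abs(pi - pi_orc)) < 1e-6

    def test_row_stochastic_and_stationary_invariants(self):
        rng = np.random.default_rng(7)
        for reversible in (True, False):
            C = np.floor(rng.random((5, 5)) * 30) + 1
            res = estimate_transition_model(C, reversible=reversible)
            T, pi = res.transition_matrix, res.stationary_distribution
            assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(pi >= 0) and pi.sum() == pytest.approx(1.0)
            assert np.allclose(pi @ T, pi, atol=1e-10)
            assert res.eigenvalues[0] == pytest.approx(1.0)

    def test_disconnected_state_gets_zero_probability(self):
        # state 2 never exchanges with {0, 1}
        C = np.array([[5.0, 3.0, 0.0], [2.0, 6.0, 0.0], [0.0, 0.0, 4.0]])
        res = estimate_transition_model(C)
        assert list(res.active_set) == [0, 1]
        assert res.stationary_distribution[2] == 0.0
        assert res.stationary_distribution.sum() == pytest.approx(1.0)

    def test_largest_connected_set_prefers_bigger_component(self):
        C = np.zeros((5, 5))
        C[0, 1] = C[1, 0] = 1  # 2-state component
        C[2, 3] = C[3, 4] = C[4, 2] = 1  # 3-state cycle
        assert list(largest_connected_set(C)) == [2, 3, 4]

    def test_empty_counts_raise(self):
        with pytest.raises(EstimationError):
            estimate_transition_model(np.zeros((3, 3)))

    def test_estimate_converges_to_generator_with_data(self, chain_sampler):
        T_true = np.array([[0.9, 0.08, 0.02], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        rng = np.random.default_rng(8)
        errs = []
        for n in (2_000, 32_000):
            states = chain_sampler(T_true, n, rng)
            res = MarkovStateModel([DiscreteTrajectory(states, 3)], lag=1,
                                   reversible=False).fit()
            errs.append(np.max(np.abs(res.transition_matrix - T_true)))
        # error should drop roughly like 1/sqrt(n): expect ~4x, accept > 2x
        assert errs[1] < errs[0] / 2


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_reversible_mle_properties_on_random_counts(seed):
    """Detailed balance, stochasticity and stationarity for random counts."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 6))
    C = np.floor(rng.random((n, n)) * 40) + 1
    T, pi = _reversible_mle(C)
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
    flux = pi[:, None] * T
    assert np.allclose(flux, flux.T, atol=1e-8)
    assert np.allclose(pi @ T, pi, atol=1e-8)


# ---------------------------------------------------------------------------
# implied timescales


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        # lambda_2 = 2p - 1; choose p so lambda_2 = exp(-1)
        p = (1 + np.exp(-1)) / 2
        C = 1e6 * np.array([[p, 1 - p], [1 - p, p]])
        res = estimate_transition_model(C, lag=1)
        assert res.timescales(1)[0] == pytest.approx(1.0, rel=1e-9)

        C2 = 1e6 * np.array([[0.95, 0.05], [0.05, 0.95]])
        res2 = estimate_transition_model(C2, lag=1)
        assert res2.timescales(1)[0] == pytest.approx(-1 / np.log(0.9), rel=1e-9)

    def test_flat_for_markovian_source(self, chain_sampler):
        T_true = np.array([[0.95, 0.04, 0.01], [0.04, 0.95, 0.01], [0.02, 0.02, 0.96]])
        lam = np.sort(np.linalg.eigvals(T_true).real)[::-1]
        rng = np.random.default_rng(9)
        dtrajs = [DiscreteTrajectory(chain_sampler(T_true, 4000, rng), 3) for _ in range(8)]
        table = implied_timescales(dtrajs, [1, 2, 5, 10], n_timescales=2)
        t_slow_expected = -1 / np.log(lam[1])
        for _, row in table.iterrows():
            assert row["its_1"] == pytest.approx(t_slow_expected, rel=0.25)

    def test_non_markovian_lumping_increases_with_lag(self, chain_sampler):
        # hidden 3-state chain observed through a non-lumpable 2-state
        # merge: the observed process is non-Markovian and its apparent
        # timescale grows with lag towards the hidden slowest timescale
        T_true = np.array([[0.98, 0.02, 0.0], [0.05, 0.90, 0.05], [0.0, 0.02, 0.98]])
        rng = np.random.default_rng(10)
        lumped = []
        for _ in range(10):
            s = chain_sampler(T_true, 6000, rng)
            lumped.append(DiscreteTrajectory(np.where(s == 0, 0, 1), 2))
        table = implied_timescales(lumped, [1, 5, 15, 30], n_timescales=1)
        its = table["its_1"].to_numpy()
        assert its[3] > its[0] * 1.2

    def test_insufficient_data_flagged_not_dropped(self):
        dtrajs = [DiscreteTrajectory(np.array([0, 1, 0, 1]), 2)]
        table = implied_timescales(dtrajs, [1, 100], n_timescales=1)
        assert len(table) == 2
        assert np.isnan(table.loc[table["lag"] == 100, "its_1"]).all()


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov


def _macro_two_blocks(n_states=4):
    labels = np.array(["active", "active", "inactive", "inactive"][:n_states], dtype=object)
    return MacrostateDefinition(labels)


class TestCKTest:
    def test_identity_chain_stays_at_one(self):
        d = [DiscreteTrajectory(np.zeros(200, dtype=int), 4),
             DiscreteTrajectory(np.full(200, 2), 4)]
        res = MarkovStateModel(d, lag=1).fit()
        ck = res.ck_test(_macro_two_blocks(), steps=3)
        assert np.allclose(ck.predicted[np.isfinite(ck.predicted)], 1.0)
        assert np.allclose(ck.estimated[np.isfinite(ck.estimated)], 1.0)

    def test_single_step_prediction_equals_estimate(self, chain_sampler):
        T_true = np.array(
            [[0.9, 0.06, 0.02, 0.02], [0.06, 0.9, 0.02, 0.02],
             [0.02, 0.02, 0.9, 0.06], [0.02, 0.02, 0.06, 0.9]]
        )
        rng = np.random.default_rng(11)
        d = [DiscreteTrajectory(chain_sampler(T_true, 3000, rng), 4) for _ in range(4)]
        res = MarkovStateModel(d, lag=1).fit()
        ck = res.ck_test(_macro_two_blocks(), steps=1)
        assert np.allclose(ck.predicted[0], ck.estimated[0], atol=1e-12)

    def test_markovian_data_within_three_error_bars(self, chain_sampler):
        T_true = np.array(
            [[0.92, 0.05, 0.02, 0.01], [0.05, 0.92, 0.01, 0.02],
             [0.02, 0.01, 0.92, 0.05], [0.01, 0.02, 0.05, 0.92]]
        )
        rng = np.random.default_rng(12)
        d = [DiscreteTrajectory(chain_sampler(T_true, 5000, rng), 4) for _ in range(6)]
        res = MarkovStateModel(d, lag=1).fit()
        ck = res.ck_test(_macro_two_blocks(), steps=5)
        assert ck.max_deviation_sigmas() < 3.0


# ---------------------------------------------------------------------------
# PCCA


class TestPCCA:
    def _block_T(self, intra=0.98, inter=0.01):
        T = np.array(
            [[intra, 1 - intra - inter, inter / 2, inter / 2],
             [1 - intra - inter, intra, inter / 2, inter / 2],
             [inter / 2, inter / 2, intra, 1 - intra - inter],
             [inter / 2, inter / 2, 1 - intra - inter, intra]]
        )
        return T / T.sum(axis=1)[:, None]

    def test_block_metastable_chain_recovered(self):
        C = 10_000 * self._block_T()
        res = estimate_transition_model(C)
        macro = res.pcca(2, microstate_values=np.array([0.0, 0.1, 2.0, 2.1]))
        assert set(macro.active_states) == {0, 1}
        assert set(macro.states("inactive")) == {2, 3}

    def test_exact_block_diagonal_gives_crisp_memberships(self):
        # decoupled chains: bypass connectivity trimming and lump directly
        from allostate.msm import MSMResults, _eigensystem
        from allostate.msm import pcca as pcca_fn

        T = np.zeros((4, 4))
        T[:2, :2] = [[0.8, 0.2], [0.2, 0.8]]
        T[2:, 2:] = [[0.6, 0.4], [0.4, 0.6]]
        pi = np.full(4, 0.25)
        w, psi = _eigensystem(T, pi, reversible=True)
        res = MSMResults(
            lag=1, frame_interval=1.0, n_states=4, counts=T, active_set=np.arange(4),
            transition_matrix=T, eigenvalues=w, eigenvectors_right=psi,
            stationary_distribution=pi, reversible=True,
        )
        macro = pcca_fn(res, 2, microstate_values=np.array([0.0, 0.0, 1.0, 1.0]))
        assert np.allclose(np.max(macro.memberships, axis=1), 1.0, atol=1e-8)
        assert set(macro.active_states) == {0, 1}
        assert set(macro.states("inactive")) == {2, 3}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        C = 10_000 * self._block_T() + rng.random((4, 4))
        values = np.array([0.0, 0.1, 2.0, 2.1])
        macro = estimate_transition_model(C).pcca(2, values)
        perm = np.array([2, 0, 3, 1])  # state i -> perm[i]
        Cp = np.zeros_like(C)
        Cp[np.ix_(perm, perm)] = C
        vp = np.zeros_like(values)
        vp[perm] = values
        macro_p = estimate_transition_model(Cp).pcca(2, vp)
        assert list(macro_p.labels[perm]) == list(macro.labels)

    def test_lower_first_feature_macrostate_is_active(self, small_swarm):
        model = fit_kmeans(small_swarm, 20, seed=0)
        dtrajs = [assign(t, model) for t in small_swarm]
        res = MarkovStateModel(dtrajs, lag=10).fit()
        macro = res.pcca(2, model.centers[:, 0])
        mean_active = model.centers[macro.active_states, 0].mean()
        mean_inactive = model.centers[macro.states("inactive"), 0].mean()
        assert mean_active < mean_inactive

    def test_double_well_basins_recovered(self, small_swarm, double_well):
        """PCCA on seeded double-well data separates the two basins."""
        model = fit_kmeans(small_swarm, 20, seed=0)
        dtrajs = [assign(t, model) for t in small_swarm]
        res = MarkovStateModel(dtrajs, lag=10).fit()
        macro = res.pcca(2, model.centers[:, 0])
        midpoint = 0.5 * (double_well.minima[0][0] + double_well.minima[1][0])
        # centres well inside each basin must be labelled consistently
        for s in range(model.n_states):
            x = model.centers[s, 0]
            if x < midpoint - 0.5:
                assert macro.labels[s] == "active"
            elif x > midpoint + 0.5:
                assert macro.labels[s] == "inactive"


def test_summary_mentions_key_quantities(small_swarm):
    model = fit_kmeans(small_swarm, 10, seed=0)
    res = MarkovStateModel([assign(t, model) for t in small_swarm], lag=5).fit()
    text = res.summary()
    assert "lag (frames):" in text and "eigenvalues" in text
    assert str(res.active_set.size) in text
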