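import numpy as np
import pytest

from fretkit import msm as M

from conftest import sample_markov_chain


class TestTica:
    def test_ar1_eigenvalue_matches_autocorrelation(self, rng):
        rho, n = 0.9, 10**5
        x = np.empty(n)
        x[0] = 0.0
        noise = rng.normal(size=n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + noise[t]
        model = M.tica_fit(x[:, None], lag=1)
        assert model.eigenvalues[0] == pytest.approx(rho, abs=0.02)

    def test_white_noise_has_no_slow_modes(self, rng):
        model = M.tica_fit(rng.normal(size=(10**5, 3)), lag=1)
        assert np.all(np.abs(model.eigenvalues) < 0.05)

    def test_eigenvalues_invariant_under_feature_rotation(self, rng):
        X = np.cumsum(rng.normal(size=(5000, 3)), axis=0) * 0.01 \
            + rng.normal(size=(5000, 3))
        from scipy.stats import ortho_group
        Q = ortho_group.rvs(3, random_state=3)
        m1 = M.tica_fit(X, lag=5)
        m2 = M.tica_fit(X @ Q, lag=5)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)

    def test_components_uncorrelated_at_lag_zero(self, rng):
        X = rng.normal(size=(20000, 4)) @ rng.normal(size=(4, 4))
        lag = 2
        model = M.tica_fit(X, lag=lag)
        Y = model.transform(X)
        # same symmetrized instantaneous-covariance estimator as the fit
        Y0, Yt = Y[:-lag], Y[lag:]
        C0 = 0.5 * (Y0.T @ Y0 + Yt.T @ Yt) / len(Y0)
        off = C0 - np.diag(np.diag(C0))
        assert np.max(np.abs(off)) < 1e-6


class TestKMeans:
    def test_separated_blobs_recover_labels(self, rng):
        from sklearn.metrics import adjusted_rand_score
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        labels_true = rng.integers(0, 3, 3000)
        X = centers[labels_true] + rng.normal(size=(3000, 2))
        dtraj, _ = M.cluster_kmeans(X, 3, seed=0)
        assert adjusted_rand_score(labels_true, dtraj) > 0.99

    def test_k_equals_n_gives_zero_inertia(self, rng):
        X = rng.normal(size=(20, 2))
        dtraj, centers = M.cluster_kmeans(X, 20, seed=0)
        assert len(np.unique(dtraj)) == 20
        np.testing.assert_allclose(np.sort(centers[dtraj], axis=0),
                                   np.sort(X, axis=0), atol=1e-12)

    def test_same_seed_same_assignment(self, rng):
        X = rng.normal(size=(500, 2))
        d1, _ = M.cluster_kmeans(X, 10, seed=42)
        d2, _ = M.cluster_kmeans(X, 10, seed=42)
        np.testing.assert_array_equal(d1, d2)


class TestEstimateMsm:
    def test_deterministic_cycle(self):
        dtraj = np.tile([0, 1, 2], 100)
        model = M.estimate_msm(dtraj, lag=1)
        expected = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        np.testing.assert_allclose(model.T, expected)
        np.testing.assert_allclose(model.pi, np.full(3, 1 / 3), atol=1e-10)

    def test_two_state_chain_recovers_rates_and_timescale(self):
        p = 0.05
        T_true = np.array([[1 - p, p], [p, 1 - p]])
        dtraj = sample_markov_chain(T_true, 10**6, seed=2024)
        model = M.estimate_msm(dtraj, lag=1)
        np.testing.assert_allclose(model.T, T_true, atol=0.002)
        # closed form: lambda_2 = 1 - 2p = 0.9 -> t = -1/ln(0.9)
        assert model.timescales(1)[0] == pytest.approx(-1 / np.log(0.9), rel=0.05)

    def test_row_stochastic_and_stationary(self, rng):
        dtraj = rng.integers(0, 5, 20000)
        model = M.estimate_msm(dtraj, lag=1)
        np.testing.assert_allclose(model.T.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(model.pi @ model.T, model.pi, atol=1e-8)
        assert model.pi.min() >= 0
        assert model.pi.sum() == pytest.approx(1.0)

    def test_reversible_agrees_with_nonreversible_on_reversible_data(self):
        # reversible 3-state chain
        pi = np.array([0.5, 0.3, 0.2])
        c = {(0, 1): 0.02, (1, 2): 0.015, (0, 2): 0.005}
        T_true = np.zeros((3, 3))
        for (i, j), x in c.items():
            T_true[i, j] = x / pi[i]
            T_true[j, i] = x / pi[j]
        np.fill_diagonal(T_true, 1 - T_true.sum(axis=1))
        dtraj = sample_markov_chain(T_true, 5 * 10**5, seed=7)
        m_rev = M.estimate_msm(dtraj, lag=1, reversible=True)
        m_non = M.estimate_msm(dtraj, lag=1, reversible=False)
        assert np.max(np.abs(m_rev.T - m_non.T) / np.maximum(m_non.T, 1e-3)) < 0.005
        # detailed balance holds for the reversible estimate
        flux = m_rev.pi[:, None] * m_rev.T
        np.testing.assert_allclose(flux, flux.T, atol=1e-6)

    def test_disconnected_trajectory_warns_and_restricts(self):
        dtraj = np.concatenate([np.tile([0, 1], 200), np.tile([2, 3], 100) + 0])
        # states {0,1} and {2,3} are bridged by one transition only (1->2),
        # so the strong component keeps the larger block
        with pytest.warns(UserWarning, match="disconnected"):
            model = M.estimate_msm(dtraj, lag=1)
        assert model.n_states == 2


class TestImpliedTimescales:
    def test_markovian_chain_is_lag_independent(self):
        p, q = 0.02, 0.04
        T_true = np.array([[1 - p, p], [q, 1 - q]])
        dtraj = sample_markov_chain(T_true, 5 * 10**5, seed=11)
        its = M.implied_timescales(dtraj, lags=[1, 2, 5, 10], n_timescales=1)
        vals = np.array([its[lag][0] for lag in (1, 2, 5, 10)])
        truth = -1 / np.log(1 - p - q)
        assert np.all(np.abs(vals - truth) / truth < 0.05)

    def test_iid_sequence_has_no_slow_timescale(self, rng):
        dtraj = rng.integers(0, 4, 10**5)
        its = M.implied_timescales(dtraj, lags=[1], n_timescales=2)
        ts = its[1]
        assert np.all(np.isnan(ts) | (ts < 1.5))

    def test_two_timescale_chain_shows_both_plateaus(self):
        # nested metastability: two slow blocks, faster intra-block exchange
        T = np.array([
            [0.990, 0.008, 0.002, 0.000],
            [0.008, 0.990, 0.000, 0.002],
            [0.002, 0.000, 0.958, 0.040],
            [0.000, 0.002, 0.040, 0.958]])
        # symmetric => uniform pi, reversible
        lam = np.sort(np.linalg.eigvals(T))[::-1]
        planted = -1 / np.log(np.real(lam[1:3]))
        dtraj = sample_markov_chain(T, 10**6, seed=5)
        its = M.implied_timescales(dtraj, lags=[2], n_timescales=2)
        np.testing.assert_allclose(its[2], planted, rtol=0.10)


class TestCkTest:
    def test_markovian_chain_passes(self):
        p = 0.02
        T_true = np.array([[1 - p, p], [p, 1 - p]])
        dtraj = sample_markov_chain(T_true, 10**6, seed=13)
        res = M.ck_test(dtraj, lag=1, multiples=[1, 2, 5], n_macro=2)
        assert res["max_deviation"] < 0.02

    def test_k_equal_one_deviation_zero(self):
        dtraj = sample_markov_chain(np.array([[0.9, 0.1], [0.1, 0.9]]), 10**4, seed=1)
        res = M.ck_test(dtraj, lag=1, multiples=[1], n_macro=2)
        assert res["max_deviation"] < 1e-12

    def test_non_markovian_dynamics_detected(self):
        # hidden 3-state chain observed through a 2-state lumping is not
        # Markovian at lag 1: CK deviation must exceed the Markovian baseline
        T_hidden = np.array([[0.98, 0.02, 0.00],
                             [0.02, 0.96, 0.02],
                             [0.00, 0.02, 0.98]])
        hidden = sample_markov_chain(T_hidden, 5 * 10**5, seed=3)
        observed = np.where(hidden == 2, 1, 0)   # lump states 0,1
        res_bad = M.ck_test(observed, lag=1, multiples=[1, 5, 10], n_macro=2)
        T_markov = np.array([[0.99, 0.01], [0.02, 0.98]])
        markov = sample_markov_chain(T_markov, 5 * 10**5, seed=3)
        res_ok = M.ck_test(markov, lag=1, multiples=[1, 5, 10], n_macro=2)
        assert res_bad["max_deviation"] > 3 * res_ok["max_deviation"]


class TestPcca:
    def test_single_set_is_trivial(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = M.MarkovModel(1, np.zeros((2, 2), dtype=np.int64), T,
                              M._stationary_distribution(T), np.arange(2))
        part = M.pcca(model, 1)
        np.testing.assert_array_equal(part.memberships, np.ones((2, 1)))

    def test_weakly_coupled_blocks_recovered(self):
        T = np.array([[0.95, 0.05, 0.00, 0.00],
                      [0.05, 0.94, 0.01, 0.00],
                      [0.00, 0.01, 0.94, 0.05],
                      [0.00, 0.00, 0.05, 0.95]])
        model = M.MarkovModel(1, np.zeros((4, 4), dtype=np.int64), T,
                              M._stationary_distribution(T), np.arange(4))
        part = M.pcca(model, 2)
        assert part.assignments[0] == part.assignments[1]
        assert part.assignments[2] == part.assignments[3]
        assert part.assignments[0] != part.assignments[2]

    def test_memberships_on_simplex(self):
        T = np.array([[0.8, 0.15, 0.05],
                      [0.10, 0.85, 0.05],
                      [0.05, 0.05, 0.90]])
        model = M.MarkovModel(1, np.zeros((3, 3), dtype=np.int64), T,
                              M._stationary_distribution(T), np.arange(3))
        part = M.pcca(model, 2)
        assert np.all(part.memberships >= 0)
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0, atol=1e-8)


class TestTpt:
    @staticmethod
    def model_from_T(T):
        return M.MarkovModel(1, np.zeros(T.shape, dtype=np.int64), T,
                             M._stationary_distribution(T), np.arange(T.shape[0]))

    def test_linear_chain_single_pathway(self):
        T = np.array([[0.9, 0.1, 0.0],
                      [0.05, 0.9, 0.05],
                      [0.0, 0.1, 0.9]])
        net = M.coarse_fluxes(self.model_from_T(T), None, [0], [2])
        paths = net.pathway_percentages()
        assert len(paths) == 1
        assert paths[0][0] == (0, 1, 2)
        assert paths[0][1] == pytest.approx(100.0)

    def test_symmetric_chain_middle_committor_half(self):
        T = np.array([[0.9, 0.1, 0.0],
                      [0.05, 0.9, 0.05],
                      [0.0, 0.1, 0.9]])
        net = M.coarse_fluxes(self.model_from_T(T), None, [0], [2])
        assert net.committor_forward[1] == pytest.approx(0.5)

    def test_diamond_branch_percentages_match_closed_form(self):
        # irreversible diamond 0 -> {1, 2} -> 3 -> 0: committors are 1 off the
        # source, so each branch flux is exactly pi_0 * T[0, branch]
        T = np.array([[0.96, 0.03, 0.01, 0.00],
                      [0.00, 0.95, 0.00, 0.05],
                      [0.00, 0.00, 0.80, 0.20],
                      [1.00, 0.00, 0.00, 0.00]])
        net = M.coarse_fluxes(self.model_from_T(T), None, [0], [3])
        pct = dict((p, x) for p, x in net.pathway_percentages())
        assert pct[(0, 1, 3)] == pytest.approx(75.0, abs=1e-6)
        assert pct[(0, 2, 3)] == pytest.approx(25.0, abs=1e-6)

    def test_total_flux_is_cut_invariant(self):
        # 5-state reversible chain: flux across every source/sink cut equal
        pi = np.array([0.3, 0.2, 0.15, 0.2, 0.15])
        c = {(0, 1): 0.01, (1, 2): 0.008, (2, 3): 0.012, (3, 4): 0.009,
             (1, 3): 0.003}
        T = np.zeros((5, 5))
        for (i, j), x in c.items():
            T[i, j] = x / pi[i]
            T[j, i] = x / pi[j]
        np.fill_diagonal(T, 1 - T.sum(axis=1))
        net = M.coarse_fluxes(self.model_from_T(T), None, [0], [4])
        f = net.micro_net_flux
        for cut in ([0], [0, 1], [0, 1, 2], [0, 1, 2, 3]):
            rest = np.setdiff1d(np.arange(5), cut)
            across = f[np.ix_(cut, rest)].sum() - f[np.ix_(rest, cut)].sum()
            assert across == pytest.approx(net.total_flux, abs=1e-8)

    def test_overlapping_source_sink_rejected(self):
        T = np.eye(3)
        with pytest.raises(ValueError):
            M.coarse_fluxes(self.model_from_T(T), None, [0], [0, 2])


class TestFel:
    def test_uniform_density_is_flat(self, rng):
        n = 200000
        fel = M.free_energy_surface(rng.random((n, 2)), grid_shape=(10, 10))
        # multinomial 3 sigma on per-bin F fluctuation
        p = 1 / 100
        sigma_F = np.sqrt((1 - p) / (n * p))
        assert np.nanmax(fel.F[np.isfinite(fel.F)]) < 3.5 * sigma_F * 2

    def test_two_basin_depth_difference(self, rng):
        pts = np.concatenate([rng.normal([0, 0], 0.3, (90000, 2)),
                              rng.normal([3, 3], 0.3, (10000, 2))])
        fel = M.free_energy_surface(pts, grid_shape=(40, 40))
        i0 = np.searchsorted(fel.x_edges, 0.0) - 1
        j0 = np.searchsorted(fel.y_edges, 0.0) - 1
        i1 = np.searchsorted(fel.x_edges, 3.0) - 1
        j1 = np.searchsorted(fel.y_edges, 3.0) - 1
        dF = fel.F[i1, j1] - fel.F[i0, j0]
        assert dF == pytest.approx(np.log(9), abs=0.2)

    def test_single_occupied_bin(self):
        fel = M.free_energy_surface(np.zeros((5, 2)), grid_shape=(4, 4))
        finite = np.isfinite(fel.F)
        assert finite.sum() == 1
        assert fel.F[finite][0] == 0.0

    def test_probability_renormalizes_to_empirical_density(self, rng):
        pts = rng.normal(size=(5000, 2))
        fel = M.free_energy_surface(pts, grid_shape=(20, 20))
        np.testing.assert_allclose(fel.probability, fel.counts / fel.counts.sum(),
                                   atol=1e-9)


class TestCosineContent:
    def test_pure_cosine_is_one(self):
        T = 10**4
        t = np.arange(T)
        X = np.column_stack([np.cos(np.pi * t / T), np.zeros(T)])
        assert M.pca_cosine_content(X, 1)[0] == pytest.approx(1.0, abs=1e-4)

    def test_white_noise_is_low(self, rng):
        cc = M.pca_cosine_content(rng.normal(size=(10**4, 2)), 2)
        assert np.all(cc < 0.05)

    def test_random_walk_flags_poor_sampling(self):
        rng = np.random.default_rng(8)
        rw = np.cumsum(rng.normal(size=(10**4, 20)), axis=0)
        assert M.pca_cosine_content(rw, 1)[0] > 0.7
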