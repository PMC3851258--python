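import numpy as np
import pytest

from dntox.errors import ParameterError
from dntox.network import (ConnectivityMatrix, Edge, EdgeSet, StateSpaceModel,
                           connectivity_matrix, ensemble_connectivity,
                           fit_state_space, rank_edges,
                           select_hidden_dimension, top_edges)
from dntox.simulate import SimulationConfig, simulate_expression, simulate_truth


def sample_lds(N=10, k=3, T=18, seed=0, obs_sd=0.1, state_sd=0.3):
    rng = np.random.default_rng(seed)
    A = 0.9 * np.linalg.qr(rng.standard_normal((k, k)))[0]
    C = rng.standard_normal((N, k))
    x = rng.standard_normal(k)
    Y = np.zeros((N, T))
    for t in range(T):
        Y[:, t] = C @ x + obs_sd * rng.standard_normal(N)
        x = A @ x + state_sd * rng.standard_normal(k)
    return Y


class TestEmFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_non_decreasing(self, seed):
        Y = sample_lds(seed=seed)
        m = fit_state_space(Y, k=3, max_iter=40, seed=seed)
        diffs = np.diff(m.loglik_trace)
        assert np.all(diffs >= -1e-6 * (1.0 + np.abs(m.loglik_trace[:-1])))

    def test_max_iter_zero_returns_initialization(self):
        Y = sample_lds()
        m = fit_state_space(Y, k=3, max_iter=0)
        assert len(m.loglik_trace) == 1

    def test_k_one_constant_data(self):
        Y = np.tile(np.linspace(1, 2, 5)[:, None], (1, 18))
        m = fit_state_space(Y, k=1, max_iter=30)
        # centered constant data leave essentially zero residual variance
        assert np.all(m.R < 1e-6)

    @pytest.mark.parametrize("k", [0, 20, 18])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ParameterError):
            fit_state_space(sample_lds(N=20), k=k)

    def test_deterministic_given_seed(self):
        Y = sample_lds(seed=2)
        a = fit_state_space(Y, k=3, max_iter=20, seed=9, restarts=2)
        b = fit_state_space(Y, k=3, max_iter=20, seed=9, restarts=2)
        np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)
        np.testing.assert_array_equal(a.A, b.A)


class TestHiddenDimension:
    def test_rank_two_data(self):
        rng = np.random.default_rng(1)
        U = rng.standard_normal((20, 2))
        V = rng.standard_normal((2, 18))
        assert select_hidden_dimension(U @ V, k_max=10) == 2

    def test_white_noise_needs_many_components(self):
        rng = np.random.default_rng(2)
        k = select_hidden_dimension(rng.standard_normal((20, 18)), k_max=17)
        assert k >= 10

    def test_zero_threshold_gives_one(self):
        rng = np.random.default_rng(3)
        assert select_hidden_dimension(rng.standard_normal((10, 18)), k_max=5,
                                       variance_threshold=0.0) == 1


class TestConnectivity:
    def model_with(self, A, C):
        k = A.shape[0]
        return StateSpaceModel(k=k, A=A, C=C, Q=np.eye(k), R=np.ones(C.shape[0]),
                               mu0=np.zeros(k), V0=np.eye(k))

    def test_identity_loading_returns_A(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        D = connectivity_matrix(self.model_with(A, np.eye(4)), list("abcd")).D
        np.testing.assert_allclose(D, A, atol=1e-10)

    def test_zero_dynamics_zero_connectivity(self):
        C = np.random.default_rng(1).standard_normal((6, 2))
        D = connectivity_matrix(self.model_with(np.zeros((2, 2)), C),
                                [f"g{i}" for i in range(6)]).D
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_permutation_equivariance(self):
        """Permuting the gene rows permutes D's rows and columns identically."""
        Y = sample_lds(N=8, seed=4)
        genes = [f"g{i}" for i in range(8)]
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        m1 = fit_state_space(Y, k=3, max_iter=30, seed=0)
        m2 = fit_state_space(Y[perm], k=3, max_iter=30, seed=0)
        D1 = connectivity_matrix(m1, genes).D
        D2 = connectivity_matrix(m2, [genes[i] for i in perm]).D
        np.testing.assert_allclose(D2, D1[np.ix_(perm, perm)], atol=1e-6)


class TestEdgeRanking:
    def test_all_pairs_ranked(self):
        rng = np.random.default_rng(0)
        conn = ConnectivityMatrix(genes=[f"g{i}" for i in range(5)],
                                  D=rng.standard_normal((5, 5)))
        ranked = rank_edges(conn)
        assert len(ranked) == 25
        strengths = [e.strength for e in ranked]
        assert strengths == sorted(strengths, reverse=True)
        assert [e.rank for e in ranked.edges] == list(range(1, 26))

    def test_single_nonzero_entry_ranks_first(self):
        D = np.zeros((3, 3))
        D[1, 2] = -0.7
        ranked = rank_edges(ConnectivityMatrix(genes=list("abc"), D=D))
        assert ranked.edges[0].pair == ("b", "c")
        assert ranked.edges[0].sign == -1

    def test_ties_broken_lexicographically(self):
        D = np.zeros((2, 2))
        D[1, 0] = 0.5
        D[0, 1] = -0.5
        ranked = rank_edges(ConnectivityMatrix(genes=["a", "b"], D=D))
        assert ranked.edges[0].pair == ("a", "b")
        assert ranked.edges[1].pair == ("b", "a")

    def test_top_edges_multiplier(self):
        rng = np.random.default_rng(1)
        conn = ConnectivityMatrix(genes=[f"g{i}" for i in range(5)],
                                  D=rng.standard_normal((5, 5)))
        assert len(top_edges(rank_edges(conn), 4)) == 20

    def test_top_edges_capped_at_all(self):
        rng = np.random.default_rng(2)
        conn = ConnectivityMatrix(genes=["a", "b"], D=rng.standard_normal((2, 2)))
        assert len(top_edges(rank_edges(conn), 4)) == 4


class TestEdgeRecovery:
    def test_var1_precision_beats_density_baseline(self):
        """On sparse first-order network dynamics the top-4N edges recover
        true edges well above the random baseline."""
        precisions = []
        for seed in range(8):
            cfg = SimulationConfig(n_genes=20, seed=seed, active_fraction=1.0)
            truth = simulate_truth(cfg)
            expr = simulate_expression(truth, cfg)
            Y = expr.observed["0"]
            k = select_hidden_dimension(Y, k_max=17)
            m = fit_state_space(Y, k=k, max_iter=50, seed=seed)
            top = top_edges(rank_edges(connectivity_matrix(m, truth.genes)), 4)
            prec = len(top.pairs() & set(truth.base_edges)) / len(top)
            precisions.append(prec)
        assert np.mean(precisions) >= 2 * cfg.edge_density

    def test_ensemble_connectivity_shapes_and_determinism(self):
        cfg = SimulationConfig(n_genes=10, seed=0, active_fraction=1.0)
        truth = simulate_truth(cfg)
        expr = simulate_expression(truth, cfg)
        mats = {lab: expr.observed[lab] for lab in ("0", "1000")}
        a = ensemble_connectivity(mats, truth.genes, k=4, n_init=3, seed=1)
        b = ensemble_connectivity(mats, truth.genes, k=4, n_init=3, seed=1)
        for lab in mats:
            assert a[lab].D.shape == (10, 10)
            np.testing.assert_array_equal(a[lab].D, b[lab].D)
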