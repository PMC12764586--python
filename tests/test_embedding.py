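import numpy as np
import pytest

from graphtad.embedding import (
    EmptyGraphError,
    NetMFConfig,
    deepwalk_matrix_approx,
    deepwalk_matrix_exact,
    matrix_to_graph,
    netmf_embed,
    shifted_log_factorize,
)


def naive_deepwalk_matrix(adj, window, neg):
    """Independent brute-force oracle: repeated dense multiplication."""
    deg = adj.sum(axis=1)
    vol = deg.sum()
    d_inv = np.diag(1.0 / deg)
    p = d_inv @ adj
    acc = np.zeros_like(adj, dtype=float)
    for r in range(1, window + 1):
        acc = acc + np.linalg.matrix_power(p, r)
    return vol / (neg * window) * acc @ d_inv


def random_connected_adjacency(rng, m):
    a = rng.random((m, m)) * 4
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    a[a < 0.5] = 0.0
    # chain edges guarantee every node is active
    for i in range(m - 1):
        a[i, i + 1] = a[i + 1, i] = max(a[i, i + 1], 1.0)
    return a


class TestMatrixToGraph:
    def test_hand_example(self):
        m = np.array([[5.0, 2, 0], [2, 5, 1], [0, 1, 5]])
        g = matrix_to_graph(m)
        np.testing.assert_array_equal(
            g.adjacency, [[0, 2, 0], [2, 0, 1], [0, 1, 0]]
        )
        np.testing.assert_array_equal(g.degrees, [2, 3, 1])
        assert g.vol == 6

    def test_zero_row_inactive(self):
        m = np.array([[0.0, 2, 0], [2, 0, 0], [0, 0, 7]])
        g = matrix_to_graph(m)  # diag zeroed -> node 2 has no edges
        np.testing.assert_array_equal(g.active_nodes, [0, 1])

    def test_zero_matrix_signals_empty_graph(self):
        with pytest.raises(EmptyGraphError):
            matrix_to_graph(np.zeros((4, 4)))

    def test_keep_diagonal_flag(self):
        m = np.array([[5.0, 2], [2, 5]])
        g = matrix_to_graph(m, keep_diagonal=True)
        assert g.vol == 14


class TestDeepwalkExact:
    def test_two_node_hand_example(self):
        g = matrix_to_graph(np.array([[0.0, 1], [1, 0]]))
        chi = deepwalk_matrix_exact(g, NetMFConfig(window=1, neg=1))
        np.testing.assert_allclose(chi, [[0, 2], [2, 0]], atol=1e-14)

    def test_window_one_is_line_matrix(self, rng):
        a = random_connected_adjacency(rng, 9)
        g = matrix_to_graph(a)
        chi = deepwalk_matrix_exact(g, NetMFConfig(window=1, neg=1))
        d_inv = np.diag(1.0 / g.degrees)
        line = g.vol * d_inv @ g.adjacency @ d_inv
        np.testing.assert_allclose(chi, (line + line.T) / 2, atol=1e-10)

    @pytest.mark.parametrize("window", [1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, rng, window):
        for m in range(3, 13):
            a = random_connected_adjacency(rng, m)
            g = matrix_to_graph(a)
            chi = deepwalk_matrix_exact(g, NetMFConfig(window=window, neg=1))
            expected = naive_deepwalk_matrix(a, window, 1)
            expected = (expected + expected.T) / 2
            assert np.abs(chi - expected).max() <= 1e-10


class TestDeepwalkApprox:
    def test_full_rank_reproduces_exact(self, rng):
        for m in range(3, 13):
            a = random_connected_adjacency(rng, m)
            g = matrix_to_graph(a)
            cfg = NetMFConfig(window=2, rank=m)
            exact = deepwalk_matrix_exact(g, cfg)
            approx = deepwalk_matrix_approx(g, cfg)
            assert np.abs(exact - approx).max() <= 1e-8

    def test_two_node_example(self):
        g = matrix_to_graph(np.array([[0.0, 1], [1, 0]]))
        chi = deepwalk_matrix_approx(g, NetMFConfig(window=1, rank=2))
        np.testing.assert_allclose(chi, [[0, 2], [2, 0]], atol=1e-12)

    def test_truncation_error_is_discarded_eigenpart(self, rng):
        a = random_connected_adjacency(rng, 8)
        g = matrix_to_graph(a)
        cfg_full = NetMFConfig(window=1, rank=8)
        cfg_1 = NetMFConfig(window=1, rank=1)
        full = deepwalk_matrix_approx(g, cfg_full)
        rank1 = deepwalk_matrix_approx(g, cfg_1)
        # the residual is exactly the discarded eigenpairs' contribution
        inv_sqrt_d = 1.0 / np.sqrt(g.degrees)
        norm_adj = g.adjacency * inv_sqrt_d[:, None] * inv_sqrt_d[None, :]
        evals, evecs = np.linalg.eigh(norm_adj)
        order = np.argsort(-np.abs(evals))
        resid = np.zeros_like(full)
        for k in order[1:]:
            u = evecs[:, k]
            resid += evals[k] * np.outer(u, u)
        resid = g.vol * (resid * inv_sqrt_d[:, None] * inv_sqrt_d[None, :])
        np.testing.assert_allclose(
            np.linalg.norm(full - rank1, "fro"),
            np.linalg.norm(resid, "fro"),
            rtol=1e-8,
        )

    def test_rank_clamped_with_warning(self, rng):
        a = random_connected_adjacency(rng, 5)
        g = matrix_to_graph(a)
        with pytest.warns(UserWarning, match="clamp"):
            deepwalk_matrix_approx(g, NetMFConfig(window=2, rank=50))


class TestShiftedLogFactorize:
    def test_two_node_hand_svd(self):
        emb, e_eff = shifted_log_factorize(np.array([[0.0, 2], [2, 0]]), 455)
        assert e_eff == 1
        expected = np.sqrt(np.log(2) / 2)
        np.testing.assert_allclose(emb, [[expected], [expected]], atol=1e-12)

    def test_sub_unit_entries_collapse_to_zero(self):
        chi = np.full((4, 4), 0.7)
        with pytest.warns(UserWarning):
            emb, e_eff = shifted_log_factorize(chi, 8)
        assert e_eff == 0 and not emb.any()

    def test_eckart_young_optimality(self, rng):
        # Frobenius residual of the rank-a factorization equals the
        # discarded singular values' energy (checked against full SVD)
        a = rng.random((12, 12)) * 3 + 0.5
        chi = (a + a.T) / 2
        log_chi = np.log(np.maximum(chi, 1.0))
        for dim in (1, 3, 6):
            emb, e_eff = shifted_log_factorize(chi, dim)
            assert e_eff == dim
            # reconstruct via the symmetric structure: L ~ U S sign(L) U^T
            sv = np.linalg.svd(log_chi, compute_uv=False)
            evals = np.linalg.eigh(log_chi)[0]
            order = np.argsort(-np.abs(evals))
            kept = evals[order[:dim]]
            evecs = np.linalg.eigh(log_chi)[1][:, order[:dim]]
            approx = evecs @ np.diag(kept) @ evecs.T
            np.testing.assert_allclose(
                np.linalg.norm(log_chi - approx, "fro") ** 2,
                (sv[dim:] ** 2).sum(),
                rtol=1e-9,
            )
            # and the embedding's gram energy matches the kept part
            np.testing.assert_allclose(
                (emb ** 2).sum(), np.abs(kept).sum(), rtol=1e-9
            )


class TestNetmfEmbed:
    def test_rank_clamps_embedding_width(self, rng):
        a = random_connected_adjacency(rng, 10)
        emb = netmf_embed(a, NetMFConfig(dim=455))
        assert emb.e_eff <= 9
        assert np.isfinite(emb.vectors).all()

    def test_permutation_equivariance(self, rng):
        a = random_connected_adjacency(rng, 8)
        perm = rng.permutation(8)
        emb = netmf_embed(a, NetMFConfig(dim=5))
        emb_p = netmf_embed(a[np.ix_(perm, perm)], NetMFConfig(dim=5))
        # pairwise distances are permutation-equivariant (signs may flip)
        def pdist(v):
            return np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
        np.testing.assert_allclose(
            pdist(emb.vectors)[np.ix_(perm, perm)], pdist(emb_p.vectors),
            atol=1e-8,
        )

    def test_bit_identical_reruns(self, rng):
        a = random_connected_adjacency(rng, 15)
        e1 = netmf_embed(a, NetMFConfig(dim=6))
        e2 = netmf_embed(a, NetMFConfig(dim=6))
        assert np.array_equal(e1.vectors, e2.vectors)

    def test_empty_graph_yields_empty_embedding(self):
        emb = netmf_embed(np.zeros((5, 5)))
        assert emb.m_active == 0 and emb.n_nodes == 5
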