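import numpy as np
import pytest

from alenet.network import (
    canonical_labels, consensus_communities, gradient_decomposition,
    louvain, louvain_finetuned, modularity, participation_coefficient,
    similarity_matrix, within_module_zscore,
)


def two_triangles():
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        W[a, b] = W[b, a] = 1.0
    return W


def _all_partitions(n):
    """Enumerate all set partitions of range(n) as label arrays."""
    def rec(elems):
        if not elems:
            yield []
            return
        first, rest = elems[0], elems[1:]
        for p in rec(rest):
            for i in range(len(p)):
                yield p[:i] + [p[i] + [first]] + p[i + 1:]
            yield p + [[first]]
    for p in rec(list(range(n))):
        lab = np.zeros(n, dtype=int)
        for c, grp in enumerate(p):
            lab[list(grp)] = c
        yield lab


def exhaustive_max_q(W, gamma=1.0):
    return max(modularity(W, lab, gamma) for lab in _all_partitions(len(W)))


class TestLouvain:
    def test_two_triangles_optimum(self):
        W = two_triangles()
        part = louvain_finetuned(W, seed=0)
        assert part.q == pytest.approx(0.5)
        assert part.n_communities == 2
        assert exhaustive_max_q(W) == pytest.approx(0.5)

    def test_uniform_graph_single_community(self):
        W = np.ones((6, 6))
        np.fill_diagonal(W, 0.0)
        part = louvain_finetuned(W, seed=0)
        assert part.n_communities == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_matrix(self):
        part = louvain(np.zeros((5, 5)), seed=0)
        assert part.n_communities == 1
        assert part.q == 0.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        W = rng.random((12, 12))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        p1 = louvain_finetuned(W, seed=42)
        p2 = louvain_finetuned(W, seed=42)
        assert np.array_equal(p1.labels, p2.labels)
        assert p1.q == p2.q

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_on_random_graphs(self, seed):
        """Fine-tuned Louvain reaches the global modularity optimum on small graphs."""
        rng = np.random.default_rng(seed)
        n = 7
        W = (rng.random((n, n)) < 0.5).astype(float) * rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        part = louvain_finetuned(W, seed=seed)
        assert part.q == pytest.approx(exhaustive_max_q(W), abs=1e-10)

    def test_matches_exhaustive_on_signed_graph(self):
        W = two_triangles()
        W[0, 3] = W[3, 0] = -0.5  # cross-community repulsion
        part = louvain_finetuned(W, seed=1)
        assert part.q == pytest.approx(exhaustive_max_q(W), abs=1e-10)

    def test_modularity_against_networkx(self):
        """Cross-check our Q against networkx's on a positive weighted graph."""
        import networkx as nx
        rng = np.random.default_rng(3)
        W = rng.random((8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3])
        G = nx.from_numpy_array(W)
        comms = [set(np.nonzero(labels == c)[0]) for c in (1, 2, 3)]
        assert modularity(W, labels) == pytest.approx(
            nx.community.modularity(G, comms, weight="weight"), abs=1e-12)


class TestConsensus:
    def test_deterministic_graph_agreement_binary(self):
        W = two_triangles()
        part, agreement, freq = consensus_communities(W, n_reps=25, seed=0)
        assert freq == 1.0
        assert set(np.unique(agreement)) <= {0.0, 1.0}
        assert np.allclose(np.diag(agreement), 1.0)
        assert np.allclose(agreement, agreement.T)
        assert part.n_communities == 2

    def test_agreement_label_invariant(self):
        # identical structure, different node order: agreement permutes along
        W = two_triangles()
        perm = np.array([3, 4, 5, 0, 1, 2])
        _, agree1, _ = consensus_communities(W, n_reps=10, seed=1)
        _, agree2, _ = consensus_communities(W[np.ix_(perm, perm)], n_reps=10, seed=1)
        assert np.allclose(agree1, agree2[np.ix_(np.argsort(perm), np.argsort(perm))])


class TestNodeMetrics:
    def test_participation_all_within_module(self):
        W = two_triangles()
        P = participation_coefficient(W, np.array([1, 1, 1, 2, 2, 2]))
        assert np.allclose(P, 0.0)

    def test_participation_even_splits(self):
        # star node 0 connected equally into two / four modules
        W = np.zeros((5, 5))
        for j in (1, 2, 3, 4):
            W[0, j] = W[j, 0] = 1.0
        P2 = participation_coefficient(W, np.array([9, 1, 1, 2, 2]))
        assert P2[0] == pytest.approx(0.5)  # 1 - 2*(1/2)^2
        P4 = participation_coefficient(W, np.array([9, 1, 2, 3, 4]))
        assert P4[0] == pytest.approx(0.75)  # 1 - 4*(1/4)^2

    def test_isolated_node_zero_with_warning(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.warns(UserWarning, match="isolated"):
            P = participation_coefficient(W, np.array([1, 1, 2]))
        assert P[2] == 0.0

    def test_zscore_regular_module_zero(self):
        W = two_triangles()
        z = within_module_zscore(W, np.array([1, 1, 1, 2, 2, 2]))
        assert np.allclose(z, 0.0)

    def test_zscore_hub_has_module_max(self):
        # module of 4: node 0 connected to all, others in a chain
        W = np.zeros((4, 4))
        for j in (1, 2, 3):
            W[0, j] = W[j, 0] = 1.0
        z = within_module_zscore(W, np.ones(4, dtype=int))
        assert z[0] == z.max()
        assert z[0] > 0

    def test_zscore_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        W = rng.random((6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        lab = np.array([1, 1, 1, 2, 2, 2])
        perm = np.array([5, 3, 4, 0, 2, 1])
        z = within_module_zscore(W, lab)
        zp = within_module_zscore(W[np.ix_(perm, perm)], lab[perm])
        assert np.allclose(zp, z[perm])

    def test_singleton_module_warns(self):
        W = two_triangles()
        with pytest.warns(UserWarning, match="singleton"):
            z = within_module_zscore(W, np.array([1, 1, 1, 2, 2, 3]))
        assert z[5] == 0.0


class TestSimilarity:
    def test_identical_and_negated_maps(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(100)
        maps = np.vstack([base, base, -base])
        S = similarity_matrix(maps)
        assert S[0, 1] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(-1.0)

    def test_21_nodes_give_21x21(self):
        rng = np.random.default_rng(1)
        S = similarity_matrix(rng.standard_normal((21, 500)))
        assert S.shape == (21, 21)
        assert np.allclose(S, S.T, atol=1e-12)


@pytest.fixture(scope="module")
def two_block_similarity():
    S = np.block([[np.full((4, 4), 0.8), np.full((4, 4), 0.1)],
                  [np.full((4, 4), 0.1), np.full((4, 4), 0.8)]])
    np.fill_diagonal(S, 1.0)
    return S


class TestGradients:
    def test_first_component_separates_blocks_by_sign(self, two_block_similarity):
        g = gradient_decomposition(two_block_similarity)
        signs = np.sign(g.components[:, 0])
        assert np.all(signs[:4] == signs[0])
        assert np.all(signs[4:] == -signs[0])

    @pytest.mark.parametrize("retain", [0.2, 0.3, 0.4])
    def test_block_assignment_stable_across_sparsity(self, two_block_similarity, retain):
        g = gradient_decomposition(two_block_similarity, retain_fraction=retain)
        signs = np.sign(g.components[:, 0])
        assert len(np.unique(signs[:4])) == 1
        assert len(np.unique(signs[4:])) == 1
        assert signs[0] != signs[4]

    def test_pca_components_orthogonal(self):
        rng = np.random.default_rng(2)
        S = rng.standard_normal((10, 10))
        S = (S + S.T) / 2
        g = gradient_decomposition(S, retain_fraction=1.0, k=3)
        gram = g.components.T @ g.components
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_explained_variance_non_increasing(self, two_block_similarity):
        g = gradient_decomposition(two_block_similarity, k=3)
        assert np.all(np.diff(g.explained_variance) <= 1e-12)
        assert g.explained_variance.sum() <= 1 + 1e-12

    def test_identity_like_matrix_uniform_spectrum(self):
        S = np.eye(8)
        g = gradient_decomposition(S, retain_fraction=1.0, k=3)
        # no shared structure: no component dominates
        assert g.explained_variance[0] < 0.35

    def test_k_truncated_with_warning(self):
        S = np.eye(3)
        with pytest.warns(UserWarning, match="truncating"):
            g = gradient_decomposition(S, k=10)
        assert g.components.shape[1] == 2

    def test_diffusion_method_runs_and_orients(self, two_block_similarity):
        g = gradient_decomposition(two_block_similarity, method="diffusion",
                                   retain_fraction=0.5)
        assert g.components.shape == (8, 3)
        assert g.components[0, 0] >= 0


def test_canonical_labels_order_of_first_appearance():
    assert canonical_labels(np.array([7, 7, 3, 7, 3, 9])).tolist() == [1, 1, 2, 1, 2, 3]
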