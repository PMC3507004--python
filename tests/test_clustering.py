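"""Similarity measures, UPGMA merge sequences, and tree cutting.

The load-bearing check is exact merge-sequence agreement with a naive
UPGMA oracle that recomputes every cluster-pair distance as the mean over
all original leaf-pair distances (no Lance-Williams shortcut) and applies
the same node-id tie-break.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import cosine as scipy_cosine, pdist

from icamod import cut_tree, hca, pearson, uncentered_correlation
from icamod.clustering import DegenerateInputError


def naive_upgma(dist):
    """Exhaustive average-linkage oracle over the original distance matrix."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                key = (d, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        d, a, b = best
        node = n + t
        merges.append((node, a, b, 1.0 - d))
        clusters[node] = clusters.pop(a) + clusters.pop(b)
    return merges


def uncentered_distance_matrix(values):
    unit = values / np.linalg.norm(values, axis=1, keepdims=True)
    d = 1.0 - np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


class TestUncenteredCorrelation:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 0), (0, 1), 0.0),
            ((1, 2), (2, 1), 0.8),  # 4 / sqrt(5*5)
        ],
    )
    def test_hand_computed_values(self, x, y, expected):
        assert uncentered_correlation(x, y) == pytest.approx(expected)

    def test_zero_norm_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            uncentered_correlation([0, 0], [1, 2])

    def test_matches_scipy_cosine_similarity(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            assert uncentered_correlation(x, y) == pytest.approx(
                1.0 - scipy_cosine(x, y), abs=1e-12
            )

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20))
    def test_equals_pearson_on_zero_mean_vectors(self, raw):
        x = np.asarray(raw) - np.mean(raw)
        rng = np.random.default_rng(len(raw))
        y = rng.normal(size=x.size)
        y = y - y.mean()
        if np.linalg.norm(x) < 1e-6 or x.std() == 0:
            return
        assert uncentered_correlation(x, y) == pytest.approx(pearson(x, y), abs=1e-12)


class TestHca:
    def test_forced_geometry_three_genes(self):
        sig = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
        dendro = hca(sig, ["g1", "g2", "g3"])
        assert dendro.merges[0].similarity == pytest.approx(1.0)
        assert {dendro.merges[0].left, dendro.merges[0].right} == {0, 1}
        assert dendro.merges[1].similarity == pytest.approx(0.0)
        cut = cut_tree(dendro, n_clusters=2)
        assert cut.labels["g1"] == cut.labels["g2"] != cut.labels["g3"]

    def test_four_point_merge_sequence_matches_hand_oracle(self):
        sig = np.array([[1, 0.1], [1, 0.2], [0.1, 1], [-1, 0.3]], dtype=float)
        dendro = hca(sig, list("abcd"))
        oracle = naive_upgma(uncentered_distance_matrix(sig))
        got = [(m.node, m.left, m.right, m.similarity) for m in dendro.merges]
        for (n1, l1, r1, s1), (n2, l2, r2, s2) in zip(got, oracle):
            assert (n1, l1, r1) == (n2, l2, r2)
            assert s1 == pytest.approx(s2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_merge_sequence_equals_naive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 7)
        sig = rng.normal(size=(n, 3))
        dendro = hca(sig, [f"g{i}" for i in range(n)])
        oracle = naive_upgma(uncentered_distance_matrix(sig))
        for m, (node, left, right, sim) in zip(dendro.merges, oracle):
            assert (m.node, m.left, m.right) == (node, left, right)
            assert m.similarity == pytest.approx(sim, abs=1e-9)

    def test_merge_heights_match_scipy_average_linkage(self, rng):
        sig = rng.normal(size=(12, 4))
        dendro = hca(sig, [f"g{i}" for i in range(12)])
        z = scipy_linkage(pdist(sig, metric="cosine"), method="average")
        ours = sorted(1.0 - m.similarity for m in dendro.merges)
        assert np.allclose(ours, sorted(z[:, 2]), atol=1e-9)

    def test_flat_clusters_invariant_to_row_permutation(self, rng):
        sig = rng.normal(size=(10, 3))
        ids = [f"g{i}" for i in range(10)]
        base = cut_tree(hca(sig, ids), n_clusters=3)
        perm = rng.permutation(10)
        cut = cut_tree(hca(sig[perm], [ids[i] for i in perm]), n_clusters=3)
        base_sets = {frozenset(g for g, c in base.labels.items() if c == k) for k in range(3)}
        perm_sets = {frozenset(g for g, c in cut.labels.items() if c == k) for k in range(3)}
        assert base_sets == perm_sets

    def test_merge_similarities_are_non_increasing(self, rng):
        sig = rng.normal(size=(25, 4))
        sims = [m.similarity for m in hca(sig, [f"g{i}" for i in range(25)]).merges]
        assert all(a >= b - 1e-9 for a, b in zip(sims, sims[1:]))

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hca(np.ones((1, 3)), ["g"])

    def test_zero_norm_row_names_the_gene(self):
        sig = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(DegenerateInputError, match="gBAD"):
            hca(sig, ["g1", "gBAD", "g3"])

    def test_pearson_similarity_mode(self):
        sig = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.1], [3.0, 2.0, 1.0]])
        dendro = hca(sig, ["a", "b", "c"], similarity="pearson")
        assert {dendro.merges[0].left, dendro.merges[0].right} == {0, 1}


class TestCutTree:
    @pytest.fixture
    def dendro(self, rng):
        return hca(rng.normal(size=(8, 3)), [f"g{i}" for i in range(8)])

    def test_one_cluster_gathers_everything(self, dendro):
        cut = cut_tree(dendro, n_clusters=1)
        assert cut.n_clusters == 1 and set(cut.labels.values()) == {0}

    def test_n_clusters_equal_leaves_gives_singletons(self, dendro):
        cut = cut_tree(dendro, n_clusters=8)
        assert sorted(cut.labels.values()) == list(range(8))

    def test_similarity_threshold_above_all_merges_gives_singletons(self, dendro):
        top = max(m.similarity for m in dendro.merges)
        assert cut_tree(dendro, min_similarity=min(1.0, top + 1e-6)).n_clusters == 8

    def test_requires_exactly_one_criterion(self, dendro):
        with pytest.raises(ValueError):
            cut_tree(dendro)
        with pytest.raises(ValueError):
            cut_tree(dendro, n_clusters=2, min_similarity=0.5)

    def test_cluster_count_out_of_range_rejected(self, dendro):
        with pytest.raises(ValueError):
            cut_tree(dendro, n_clusters=9)
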