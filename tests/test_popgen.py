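"""F_ST, Nei distance, informativeness, NJ trees and ordination."""

import io as _io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dippanel import synth
from dippanel.io import DistanceMatrix, FrequencyTable, ParameterError, estimate_frequencies
from dippanel.popgen import (
    classical_mds,
    informativeness_for_assignment,
    informativeness_table,
    nei_standard_distance,
    neighbor_joining,
    pairwise_fst,
    pca,
    pca_individuals,
    weir_cockerham_theta,
)


def _merge(ds_list):
    from dippanel.io import GenotypeDataset

    return GenotypeDataset(
        ds_list[0].loci,
        pd.concat([d.samples for d in ds_list], ignore_index=True),
        np.vstack([d.calls for d in ds_list]),
    )


class TestFst:
    def test_null_two_identical_populations(self):
        p = np.full(50, 0.5)
        a = synth.simulate_population(p, 500, seed=1, population="A")
        b = synth.simulate_population(p, 500, seed=2, population="B")
        theta = weir_cockerham_theta(_merge([a, b]), ["A", "B"])
        assert -0.01 <= theta <= 0.01

    def test_fixed_difference_gives_theta_one(self):
        a = synth.simulate_population(np.array([1.0]), 40, seed=0, population="A")
        b = synth.simulate_population(np.array([0.0]), 40, seed=0, population="B")
        theta = weir_cockerham_theta(_merge([a, b]), ["A", "B"])
        assert theta == pytest.approx(1.0, abs=1e-12)

    def test_balding_nichols_calibration(self):
        """Multi-locus theta recovers the generating F = 0.10 at n = 500 x 2."""
        rng = np.random.default_rng(10)
        spec = synth.StructureSpec(
            ancestral_freqs=tuple(rng.uniform(0.2, 0.8, 43)),
            fst_per_pop={"A": 0.10, "B": 0.10},
            sizes={"A": 500, "B": 500},
            seed=11,
        )
        ds = synth.simulate_structured_populations(spec)
        dm = pairwise_fst(ds)
        assert dm.metric_name == "fst"
        assert 0.05 <= dm.values[0, 1] <= 0.15

    def test_matrix_symmetric_zero_diagonal(self):
        spec = synth.StructureSpec(
            ancestral_freqs=(0.3, 0.5, 0.7),
            fst_per_pop={"A": 0.05, "B": 0.05, "C": 0.05},
            sizes={"A": 60, "B": 60, "C": 60},
            seed=3,
        )
        dm = pairwise_fst(synth.simulate_structured_populations(spec))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_single_population_rejected(self):
        ds = synth.simulate_population(np.array([0.5]), 10, seed=0)
        with pytest.raises(ParameterError):
            pairwise_fst(ds)


class TestNei:
    def test_identical_populations_zero(self):
        p = np.array([0.2, 0.5, 0.9])
        assert nei_standard_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_single_locus(self):
        d = nei_standard_distance(np.array([0.9]), np.array([0.1]))
        assert d == pytest.approx(-math.log(0.18 / 0.82), abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=10),
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=10),
    )
    @settings(derandomize=True, max_examples=50)
    def test_symmetric(self, xs, ys):
        k = min(len(xs), len(ys))
        x, y = np.array(xs[:k]), np.array(ys[:k])
        assert nei_standard_distance(x, y) == pytest.approx(
            nei_standard_distance(y, x), abs=1e-12
        )


class TestInformativeness:
    def test_zero_iff_identical_frequencies(self):
        assert informativeness_for_assignment(np.array([0.4, 0.4, 0.4])) == 0.0
        assert informativeness_for_assignment(np.array([0.4, 0.41])) > 0.0

    def test_hand_computed_two_population_case(self):
        val = informativeness_for_assignment(np.array([0.9, 0.1]))
        assert val == pytest.approx(0.3681, abs=5e-5)

    def test_single_population_zero(self):
        assert informativeness_for_assignment(np.array([0.73])) == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabeling_invariance(self):
        p = np.array([0.2, 0.6, 0.9])
        assert informativeness_for_assignment(p) == pytest.approx(
            informativeness_for_assignment(1 - p), abs=1e-12
        )

    def test_log_base_config(self):
        p = np.array([0.9, 0.1])
        nats = informativeness_for_assignment(p)
        bits = informativeness_for_assignment(p, base=2)
        assert bits == pytest.approx(nats / math.log(2), abs=1e-12)

    def test_table_ranking(self):
        table = FrequencyTable(
            pd.DataFrame(
                {
                    "locus": ["l1", "l1", "l2", "l2"],
                    "population": ["A", "B", "A", "B"],
                    "p_del": [0.5, 0.5, 0.9, 0.1],
                    "n": [10, 10, 10, 10],
                }
            )
        )
        df = informativeness_table(table)
        assert df.iloc[0]["locus"] == "l2" and df.iloc[0]["rank"] == 1
        assert df.iloc[1]["In"] == pytest.approx(0.0, abs=1e-12)


def _patristic(newick: str, labels):
    """Tip-to-tip path distances of a Newick tree via scikit-bio (oracle route)."""
    from skbio import TreeNode

    tree = TreeNode.read(_io.StringIO(newick))
    dm = tree.tip_tip_distances(labels)
    return np.asarray(dm.data)


def _random_additive_matrix(rng, n_taxa):
    """Distance matrix generated from a random tree (random topology/branches).

    Built by sequential leaf attachment on an explicit edge list; leaf-to-leaf
    path lengths are additive by construction.
    """
    import itertools

    counter = itertools.count(1)
    edges = {}

    def add_edge(a, b, w):
        edges.setdefault(a, []).append((b, w))
        edges.setdefault(b, []).append((a, w))

    leaves = []
    # start from a 2-leaf tree
    root = next(counter)
    l1, l2 = next(counter), next(counter)
    add_edge(root, l1, rng.uniform(0.1, 1.0))
    add_edge(root, l2, rng.uniform(0.1, 1.0))
    leaves = [l1, l2]
    while len(leaves) < n_taxa:
        # split a random existing leaf edge and hang a new leaf
        leaf = leaves[rng.integers(len(leaves))]
        (parent, w) = edges[leaf][0]
        edges[leaf].remove((parent, w))
        edges[parent].remove((leaf, w))
        mid, new_leaf = next(counter), next(counter)
        cut = rng.uniform(0.2, 0.8) * w
        add_edge(parent, mid, cut)
        add_edge(mid, leaf, w - cut)
        add_edge(mid, new_leaf, rng.uniform(0.1, 1.0))
        leaves.append(new_leaf)

    def dist(a, b):
        # BFS path length
        stack = [(a, 0.0, None)]
        while stack:
            node, acc, prev = stack.pop()
            if node == b:
                return acc
            for nxt, w in edges.get(node, []):
                if nxt != prev:
                    stack.append((nxt, acc + w, node))
        raise RuntimeError

    k = len(leaves)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = dist(leaves[i], leaves[j])
    labels = [f"t{i}" for i in range(k)]
    return DistanceMatrix(labels, mat)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        tree = neighbor_joining(dm)
        got = _patristic(tree.newick(decimals=10), ["A", "B", "C"])
        assert np.allclose(got, dm.values, atol=1e-8)

    def test_four_taxon_additive_recovery(self):
        # quartet ((A:1,B:2):1,(C:3,D:1)) — additive by construction
        dm = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [
                    [0, 3, 5, 3],
                    [3, 0, 6, 4],
                    [5, 6, 0, 4],
                    [3, 4, 4, 0],
                ],
                dtype=float,
            ),
        )
        tree = neighbor_joining(dm)
        got = _patristic(tree.newick(decimals=10), ["A", "B", "C", "D"])
        assert np.allclose(got, dm.values, atol=1e-8)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_random_additive_trees_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            dm = _random_additive_matrix(rng, n_taxa)
            tree = neighbor_joining(dm)
            got = _patristic(tree.newick(decimals=10), dm.labels)
            assert np.allclose(got, dm.values, atol=1e-6)
            assert tree.negative_branches_adjusted == 0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(42)
        dm = _random_additive_matrix(rng, 6)
        order = rng.permutation(len(dm.labels))
        dm_perm = DistanceMatrix(
            [dm.labels[i] for i in order], dm.values[np.ix_(order, order)]
        )
        t1 = _patristic(neighbor_joining(dm).newick(decimals=10), dm.labels)
        t2 = _patristic(neighbor_joining(dm_perm).newick(decimals=10), dm.labels)
        assert np.allclose(t1, t2, atol=1e-8)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ParameterError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestMDS:
    def test_recovers_distances_from_planar_points(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"p{i}" for i in range(10)], d)
        ord_ = classical_mds(dm, dims=2)
        emb = ord_.coordinates
        d2 = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        assert np.allclose(d2, d, atol=1e-8)

    def test_all_zero_distances(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        ord_ = classical_mds(dm, dims=2)
        assert np.allclose(ord_.coordinates, 0.0)

    def test_variance_fractions_sum_to_at_most_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ord_ = classical_mds(DistanceMatrix([f"p{i}" for i in range(8)], d), dims=2)
        assert 0 < ord_.variance_fractions.sum() <= 1 + 1e-9


class TestPCA:
    def test_separated_populations_split_on_pc1(self):
        from sklearn.metrics import silhouette_score

        spec = synth.StructureSpec(
            ancestral_freqs=tuple(np.full(43, 0.5)),
            fst_per_pop={"A": 0.25, "B": 0.25},
            sizes={"A": 100, "B": 100},
            seed=21,
        )
        ds = synth.simulate_structured_populations(spec)
        ord_ = pca_individuals(ds, dims=2)
        labels = ds.samples["population"].to_numpy()
        assert silhouette_score(ord_.coordinates[:, :1], labels) > 0.5

    def test_variance_fractions_non_increasing(self):
        rng = np.random.default_rng(2)
        ord_ = pca(rng.normal(size=(20, 5)), [f"r{i}" for i in range(20)], dims=5)
        f = ord_.variance_fractions
        assert all(a >= b - 1e-12 for a, b in zip(f, f[1:]))

    def test_duplicating_rows_preserves_fractions(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 4))
        f1 = pca(x, [f"r{i}" for i in range(10)], dims=3).variance_fractions
        xx = np.vstack([x, x])
        f2 = pca(xx, [f"r{i}" for i in range(20)], dims=3).variance_fractions
        assert np.allclose(f1, f2, atol=1e-9)

    def test_constant_matrix_no_nan(self):
        out = pca(np.ones((5, 3)), list("abcde"), dims=2)
        assert not np.isnan(out.coordinates).any()
        assert not np.isnan(out.variance_fractions).any()
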