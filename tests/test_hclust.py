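"""Agglomeration under seven linkages, cophenetic distances, CCC, newick."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from _oracles import naive_agglomerate
from heterogroup.distance import DistanceMatrix
from heterogroup.hclust import (
    LINKAGES,
    MergeTree,
    agglomerate,
    ccc,
    ccc_grid,
    cophenetic,
    cut_tree,
    to_newick,
)


def three_leaf():
    vals = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
    return DistanceMatrix(labels=["A", "B", "C"], values=vals)


def merge_sets(tree: MergeTree):
    n = tree.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for idx, (left, right, h) in enumerate(tree.merges):
        members[n + idx] = members[left] | members[right]
        out.append((members[n + idx], h))
    return out


class TestAgglomerate:
    def test_average_linkage_worked_example(self):
        t = agglomerate(three_leaf(), "average")
        assert t.merges[0][:2] == (0, 1) and t.merges[0][2] == pytest.approx(1.0)
        assert t.merges[1][2] == pytest.approx(4.5)

    def test_single_linkage_worked_example(self):
        t = agglomerate(three_leaf(), "single")
        assert t.merges[1][2] == pytest.approx(4.0)

    def test_two_leaves(self):
        d = DistanceMatrix(labels=["A", "B"], values=[[0, 0.7], [0.7, 0]])
        t = agglomerate(d, "complete")
        assert t.merges == [(0, 1, 0.7)]

    @pytest.mark.parametrize("linkage", LINKAGES)
    def test_matches_naive_first_principles(self, linkage):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            vals = squareform(pdist(rng.random((n, 3))))
            d = DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=vals)
            mine = merge_sets(agglomerate(d, linkage))
            oracle = naive_agglomerate(vals, linkage)
            for (ma, ha), (mo, ho) in zip(mine, oracle):
                assert ma == mo
                assert ha == pytest.approx(ho, abs=1e-9)

    @pytest.mark.parametrize(
        "linkage,scipy_name",
        [("single", "single"), ("complete", "complete"), ("average", "average"),
         ("mcquitty", "weighted"), ("centroid", "centroid"), ("median", "median"),
         ("ward_d2", "ward")],
    )
    def test_heights_match_scipy(self, linkage, scipy_name):
        rng = np.random.default_rng(3)
        cond = pdist(rng.random((12, 4)))
        d = DistanceMatrix(labels=[f"s{i}" for i in range(12)], values=squareform(cond))
        mine = sorted(h for _, _, h in agglomerate(d, linkage).merges)
        theirs = sorted(scipy_linkage(cond, method=scipy_name)[:, 2])
        np.testing.assert_allclose(mine, theirs, atol=1e-9)

    def test_single_le_average_le_complete_heights(self):
        rng = np.random.default_rng(8)
        vals = squareform(pdist(rng.random((10, 3))))
        d = DistanceMatrix(labels=[f"s{i}" for i in range(10)], values=vals)
        hs = {lk: sorted(h for _, _, h in agglomerate(d, lk).merges)
              for lk in ("single", "average", "complete")}
        assert all(a <= b + 1e-12 for a, b in zip(hs["single"], hs["average"]))
        assert all(a <= b + 1e-12 for a, b in zip(hs["average"], hs["complete"]))

    def test_nan_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        d = DistanceMatrix(labels=["a", "b"], values=vals)
        with pytest.raises(ValueError, match="NaN"):
            agglomerate(d, "average")

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValueError, match="linkage"):
            agglomerate(three_leaf(), "wpgmc")

    def test_tie_break_deterministic(self):
        vals = np.ones((4, 4)) - np.eye(4)  # all distances equal
        d = DistanceMatrix(labels=list("abcd"), values=vals)
        t1 = agglomerate(d, "average")
        t2 = agglomerate(d, "average")
        assert t1.merges == t2.merges
        assert t1.merges[0][:2] == (0, 1)  # smallest (row, col) pair first


class TestCophenetic:
    def test_worked_example(self):
        c = cophenetic(agglomerate(three_leaf(), "average"))
        assert c.values[0, 1] == pytest.approx(1.0)
        assert c.values[0, 2] == c.values[1, 2] == pytest.approx(4.5)
        assert np.all(np.diag(c.values) == 0)

    def test_two_leaf_equals_input(self):
        d = DistanceMatrix(labels=["a", "b"], values=[[0, 0.3], [0.3, 0]])
        assert cophenetic(agglomerate(d, "single")).values[0, 1] == pytest.approx(0.3)

    def test_single_linkage_cophenetic_below_input(self):
        rng = np.random.default_rng(5)
        vals = squareform(pdist(rng.random((9, 3))))
        d = DistanceMatrix(labels=[f"s{i}" for i in range(9)], values=vals)
        c = cophenetic(agglomerate(d, "single"))
        assert np.all(c.values <= vals + 1e-12)

    def test_ultrametric_input_reproduced(self):
        # an ultrametric matrix is represented perfectly by single linkage
        vals = np.array(
            [[0, 1, 3, 3], [1, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        d = DistanceMatrix(labels=list("abcd"), values=vals)
        c = cophenetic(agglomerate(d, "single"))
        np.testing.assert_allclose(c.values, vals, atol=1e-12)


class TestCcc:
    def test_perfect_representation(self):
        vals = np.array(
            [[0, 1, 3, 3], [1, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        d = DistanceMatrix(labels=list("abcd"), values=vals)
        assert ccc(d, cophenetic(agglomerate(d, "single"))) == pytest.approx(1.0)

    def test_hand_pearson_worked_example(self):
        d = three_leaf()
        value = ccc(d, cophenetic(agglomerate(d, "average")))
        assert value == pytest.approx(0.9707, abs=1e-4)

    def test_constant_cophenetic_undefined(self):
        d = three_leaf()
        c = DistanceMatrix(labels=d.labels, values=np.full((3, 3), 2.0) - 2 * np.eye(3))
        assert np.isnan(ccc(d, c))

    def test_invariant_to_positive_affine_transform(self):
        rng = np.random.default_rng(6)
        vals = squareform(pdist(rng.random((8, 3))))
        d = DistanceMatrix(labels=[f"s{i}" for i in range(8)], values=vals)
        c = cophenetic(agglomerate(d, "average"))
        base = ccc(d, c)
        d2 = DistanceMatrix(labels=d.labels, values=3.0 * vals)
        assert ccc(d2, c) == pytest.approx(base)


class TestCccGrid:
    def test_grid_composes_from_parts(self, small_panel):
        from heterogroup.distance import genetic_distance

        g, _ = small_panel
        sub = g.subset(sample_idx=range(12))
        grid = ccc_grid(sub, metrics=["ibs", "euclidean"], linkages=["average", "single"])
        for i, metric in enumerate(["ibs", "euclidean"]):
            d = genetic_distance(sub, metric)
            for j, lk in enumerate(["average", "single"]):
                expected = ccc(d, cophenetic(agglomerate(d, lk)))
                assert grid.values[i, j] == pytest.approx(expected)
        assert grid.best_value == np.nanmax(grid.values)

    def test_single_cell_grid(self, small_panel):
        g, _ = small_panel
        sub = g.subset(sample_idx=range(8))
        grid = ccc_grid(sub, metrics=["ibs"], linkages=["average"])
        assert grid.values.shape == (1, 1)
        assert grid.best_metric == "ibs" and grid.best_linkage == "average"


class TestCutTree:
    def test_k_extremes(self):
        t = agglomerate(three_leaf(), "average")
        assert list(cut_tree(t, 1)) == [1, 1, 1]
        assert list(cut_tree(t, 3)) == [1, 2, 3]

    def test_k2_splits_highest_merge(self):
        t = agglomerate(three_leaf(), "average")
        assert list(cut_tree(t, 2)) == [1, 1, 2]

    def test_out_of_range(self):
        t = agglomerate(three_leaf(), "average")
        with pytest.raises(ValueError):
            cut_tree(t, 4)


class TestNewick:
    def test_two_leaf(self):
        d = DistanceMatrix(labels=["A", "B"], values=[[0, 2.0], [2.0, 0]])
        s = to_newick(agglomerate(d, "average"))
        assert s in ("(A:2,B:2);", "(B:2,A:2);")

    def test_three_leaf_branch_lengths(self):
        s = to_newick(agglomerate(three_leaf(), "average"))
        assert ":3.5" in s and ":4.5" in s and s.endswith(";")

    def test_round_trip_preserves_cophenetic_distances(self):
        from io import StringIO

        from Bio import Phylo

        rng = np.random.default_rng(10)
        vals = squareform(pdist(rng.random((7, 3))))
        d = DistanceMatrix(labels=[f"s{i}" for i in range(7)], values=vals)
        t = agglomerate(d, "average")
        c = cophenetic(t)
        tree = Phylo.read(StringIO(to_newick(t)), "newick")
        for i in range(7):
            for j in range(i + 1, 7):
                # patristic distance in an ultrametric tree = 2 x merge height
                path = tree.distance(f"s{i}", f"s{j}")
                assert path == pytest.approx(2 * c.values[i, j], abs=1e-6)
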