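import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from hamclust.hamming import DistanceMatrix
from hamclust.clustering import (
    Dendrogram,
    agglomerate,
    set_distance_upgma,
    set_distance_ward,
    ward_q,
)


def dm_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(len(values)))
    return DistanceMatrix(tuple(ids), values)


def random_dm(rng, n):
    """Random metric distance matrix (Euclidean on random points)."""
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return dm_from(d)


class TestSetDistances:
    def test_upgma_singletons_return_raw_distance(self):
        dm = dm_from([[0, 7], [7, 0]], ("a", "b"))
        assert set_distance_upgma(["a"], ["b"], dm) == 7

    def test_upgma_mean(self):
        dm = dm_from([[0, 2, 4], [2, 0, 9], [4, 9, 0]], ("a", "b", "c"))
        assert set_distance_upgma(["a"], ["b", "c"], dm) == 3

    def test_empty_set_convention(self):
        dm = dm_from([[0, 1], [1, 0]], ("a", "b"))
        assert set_distance_upgma([], ["a"], dm) == 0
        assert set_distance_ward([], ["a"], dm) == 0

    def test_ward_singleton_identity(self):
        dm = dm_from([[0, 10], [10, 0]], ("a", "b"))
        assert set_distance_ward(["a"], ["b"], dm) == pytest.approx(10 / math.sqrt(2), abs=1e-12)
        assert ward_q(["a"], ["b"], dm) == pytest.approx(50.0, abs=1e-12)

    def test_ward_hand_evaluated_three_samples(self):
        # all pairwise distances 2: Q = (4+4)/3 - 4/6 = 2
        dm = dm_from([[0, 2, 2], [2, 0, 2], [2, 2, 0]], ("a", "b", "c"))
        assert ward_q(["a", "b"], ["c"], dm) == pytest.approx(2.0, abs=1e-12)
        assert set_distance_ward(["a", "b"], ["c"], dm) == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_overlapping_sets_rejected(self):
        dm = dm_from([[0, 1], [1, 0]], ("a", "b"))
        with pytest.raises(ValueError, match="overlap"):
            set_distance_ward(["a"], ["a", "b"], dm)


class TestAgglomerate:
    def test_three_sample_hand_trace_upgma(self):
        dm = dm_from([[0, 1, 5], [1, 0, 5], [5, 5, 0]], ("s1", "s2", "s3"))
        dn = agglomerate(dm, "upgma")
        assert dn.cluster(4) == ("s1", "s2")
        assert dn.merges[0].height == 1
        assert dn.merges[1].height == 5
        # root = C3 ∪ C4 with tau' = 3 < tau'' = 4, so s3 leads the ordering
        assert dn.leaf_order == ("s3", "s1", "s2")

    def test_all_equal_distances_use_lexicographic_tiebreak(self):
        d = np.ones((4, 4)) - np.eye(4)
        dn = agglomerate(dm_from(d), "upgma")
        assert (dn.merges[0].tau1, dn.merges[0].tau2) == (1, 2)
        assert (dn.merges[1].tau1, dn.merges[1].tau2) == (3, 4)
        dn2 = agglomerate(dm_from(d), "upgma")
        assert [(m.tau1, m.tau2) for m in dn.merges] == [(m.tau1, m.tau2) for m in dn2.merges]

    def test_merged_member_order_concatenates_operands(self):
        dm = dm_from([[0, 1, 5], [1, 0, 5], [5, 5, 0]], ("x", "y", "z"))
        dn = agglomerate(dm, "ward")
        assert dn.cluster(4) == ("x", "y")
        assert dn.cluster(5) == ("z", "x", "y")  # C3's order, then C4's
        assert dn.offspring(5) == frozenset({"x", "y", "z"})

    @pytest.mark.parametrize("method", ["ward", "upgma"])
    def test_fast_path_equals_direct_set_formula_oracle(self, method):
        """Lance-Williams updates must reproduce direct evaluation of the
        set-distance formulas at every step: 100 random n<=8 matrices."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            dm = random_dm(rng, int(rng.integers(2, 9)))
            fast = agglomerate(dm, method)
            direct = agglomerate(dm, method, direct=True)
            assert [(m.tau1, m.tau2) for m in fast.merges] == [
                (m.tau1, m.tau2) for m in direct.merges
            ]
            np.testing.assert_allclose(fast.heights(), direct.heights(), atol=1e-10)

    @pytest.mark.parametrize(
        "method,scipy_method,scale",
        [
            ("ward", "ward", 2**-0.5),
            ("upgma", "average", 1.0),
            ("wpgma", "weighted", 1.0),
            ("upgmc", "centroid", 1.0),
            ("wpgmc", "median", 1.0),
        ],
    )
    def test_heights_match_scipy_linkage(self, method, scipy_method, scale):
        """Independent cross-check: merge heights agree with scipy's
        implementation of the same linkage (Ward after the sqrt(2) height
        convention rescaling)."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            dm = random_dm(rng, int(rng.integers(4, 9)))
            dn = agglomerate(dm, method)
            Z = linkage(squareform(dm.values), scipy_method)
            np.testing.assert_allclose(
                sorted(dn.heights()), sorted(Z[:, 2] * scale), atol=1e-9
            )

    @pytest.mark.parametrize("method", ["ward", "upgma"])
    def test_height_monotonicity(self, method):
        rng = np.random.default_rng(8)
        for _ in range(20):
            dn = agglomerate(random_dm(rng, 8), method)
            coords = dn.layout()
            for t, m in enumerate(dn.merges, start=1):
                parent = coords[t + dn.n_samples]
                assert parent[1] >= coords[m.tau1][1] - 1e-12
                assert parent[1] >= coords[m.tau2][1] - 1e-12

    def test_input_order_permutation_invariance(self):
        rng = np.random.default_rng(13)
        dm = random_dm(rng, 7)
        dn = agglomerate(dm, "ward")
        perm = rng.permutation(7)
        dm2 = DistanceMatrix(
            tuple(dm.ids[i] for i in perm), dm.values[np.ix_(perm, perm)]
        )
        dn2 = agglomerate(dm2, "ward")
        merged_sets = lambda d: sorted(
            (sorted(d.cluster(tau)) for tau in range(d.n_samples + 1, d.n_clusters + 1))
        )
        assert merged_sets(dn) == merged_sets(dn2)
        np.testing.assert_allclose(sorted(dn.heights()), sorted(dn2.heights()), atol=1e-9)

    def test_invalid_inputs(self):
        dm = dm_from([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            agglomerate(dm, "single")
        with pytest.raises(ValueError):
            agglomerate(DistanceMatrix(("a",), np.zeros((1, 1))), "ward")


class TestDendrogramGeometry:
    @pytest.fixture
    def dendro(self):
        dm = dm_from([[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 2], [5, 5, 2, 0]],
                     ("a", "b", "c", "d"))
        return agglomerate(dm, "upgma")

    def test_leaves_at_y_zero_and_order_positions(self, dendro):
        coords = dendro.layout()
        for tau in range(1, dendro.n_samples + 1):
            assert coords[tau][1] == 0.0
        xs = sorted(coords[tau][0] for tau in range(1, 5))
        assert xs == [1.0, 2.0, 3.0, 4.0]

    def test_parent_x_is_child_midpoint(self, dendro):
        coords = dendro.layout()
        for t, m in enumerate(dendro.merges, start=1):
            assert coords[t + 4][0] == pytest.approx(
                (coords[m.tau1][0] + coords[m.tau2][0]) / 2
            )

    def test_offspring_of_leaf_and_root(self, dendro):
        assert dendro.offspring(1) == frozenset({"a"})
        assert dendro.offspring(dendro.n_clusters) == frozenset("abcd")
        with pytest.raises(IndexError):
            dendro.offspring(8)

    def test_merge_table_roundtrip(self, dendro, tmp_path):
        f = tmp_path / "merges.tsv"
        dendro.to_merge_tsv(f)
        back = Dendrogram.from_merge_tsv(f)
        assert back.ids == dendro.ids
        assert back.heights() == dendro.heights()
        assert [(m.tau1, m.tau2) for m in back.merges] == [
            (m.tau1, m.tau2) for m in dendro.merges
        ]

    def test_newick_export_is_parseable_with_correct_leaf_depths(self, dendro):
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(dendro.to_newick()), "newick")
        depths = tree.depths()
        root_height = max(m.height for m in dendro.merges)
        for clade, depth in depths.items():
            if clade.name:  # every leaf sits at the root height below the root
                assert depth == pytest.approx(root_height, abs=1e-9)
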