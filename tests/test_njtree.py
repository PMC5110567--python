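"""Neighbor-joining, bootstrap supports, monophyly and tree-based rates."""

import numpy as np
import pytest

from oracles import (
    additive_distances,
    edge_length_map,
    least_squares_best_topology,
    random_topology,
    topology_bipartitions,
)

from barcodegap.alignments import AlignedMatrix, SampleRecord, make_partition
from barcodegap.distances import DistanceMatrix
from barcodegap.njtree import (
    bootstrap_supports,
    is_monophyletic,
    nj_construct,
    tree_discriminate,
)
from barcodegap.pwg import discrimination_rate
from barcodegap.trees import Clade, UnrootedTree, bipartition_key


def _dm(labels, D):
    return DistanceMatrix(list(labels), np.asarray(D, dtype=float))


def _tree_edge_lengths(tree):
    universe = frozenset(tree.leaf_names())
    leafsets = tree.leafsets()
    out = {}
    for clade in tree.root.iter_postorder():
        if clade is tree.root:
            continue
        key = bipartition_key(leafsets[id(clade)], universe)
        out[key] = out.get(key, 0.0) + clade.length
    return out


class TestNJ:
    def test_three_taxon_closed_form(self):
        tree = nj_construct(_dm("abc", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_four_taxon_additive_recovery(self):
        # unrooted tree: a:1, b:2 joined; c:3, d:4 joined; internal edge 2
        labels = ["a", "b", "c", "d"]
        D = [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]]
        tree = nj_construct(_dm(labels, D))
        uni = frozenset(labels)
        key = bipartition_key(frozenset("ab"), uni)
        lengths = _tree_edge_lengths(tree)
        assert key in lengths
        assert lengths[key] == pytest.approx(2.0, abs=1e-12)
        assert lengths[bipartition_key(frozenset("a"), uni)] == pytest.approx(1.0)
        assert lengths[bipartition_key(frozenset("d"), uni)] == pytest.approx(4.0)

    def test_too_small_or_undefined_rejected(self):
        with pytest.raises(ValueError):
            nj_construct(_dm("ab", [[0, 1], [1, 0]]))
        bad = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="undefined"):
            nj_construct(_dm("abc", bad))

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_additive_matrix_recovery_vs_enumeration(self, n_leaves):
        """NJ matches the exhaustive least-squares oracle on additive matrices."""
        rng = np.random.default_rng(100 + n_leaves)
        labels = [f"t{k}" for k in range(n_leaves)]
        for _ in range(15):
            edges = random_topology(n_leaves, rng)
            lengths = rng.uniform(0.1, 1.0, size=len(edges))
            D = additive_distances(edges, lengths, n_leaves)
            tree = nj_construct(_dm(labels, D))
            true_splits = topology_bipartitions(edges, labels)
            assert tree.bipartition_keys() == true_splits
            oracle_splits, oracle_lengths, rss = least_squares_best_topology(D, labels)
            assert oracle_splits == true_splits
            assert rss < 1e-18
            nj_lengths = _tree_edge_lengths(tree)
            for key, w in edge_length_map(edges, lengths, labels).items():
                assert nj_lengths[key] == pytest.approx(w, abs=1e-9)

    def test_deterministic_tie_break(self):
        # fully tied matrix: lexicographically first pair joins first
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj_construct(_dm("abcd", D))
        t2 = nj_construct(_dm("abcd", D))
        assert t1.bipartition_keys() == t2.bipartition_keys()
        key = bipartition_key(frozenset("ab"), frozenset("abcd"))
        assert key in t1.bipartition_keys()


def _quartet_alignment():
    """A quarter of the columns support ab|cd via a transition; the rest are
    constant, keeping the K2P distance well away from saturation."""
    a = "".join("A" if k % 4 == 0 else "C" for k in range(40))
    c = "".join("G" if k % 4 == 0 else "C" for k in range(40))
    return AlignedMatrix("q", ["a", "b", "c", "d"], [a, a, c, c])


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        tree = bootstrap_supports(_quartet_alignment(), B=50, seed=0)
        key = bipartition_key(frozenset("ab"), frozenset("abcd"))
        assert tree.bipartitions()[key].support == 1.0

    def test_supports_are_multiples_of_one_over_B(self):
        rng = np.random.default_rng(4)
        base = rng.choice(list("ACGT"), 60)
        rows = []
        for _ in range(6):  # lightly mutated copies of one ancestor
            r = base.copy()
            sites = rng.choice(60, size=6, replace=False)
            r[sites] = rng.choice(list("ACGT"), size=6)
            rows.append("".join(r))
        m = AlignedMatrix("r", [f"s{i}" for i in range(6)], rows)
        tree = bootstrap_supports(m, B=10, seed=1)
        for clade in tree.bipartitions().values():
            assert (clade.support * 10) == pytest.approx(round(clade.support * 10))

    def test_seed_reproducibility(self):
        m = _quartet_alignment()
        t1 = bootstrap_supports(m, B=25, seed=42)
        t2 = bootstrap_supports(m, B=25, seed=42)
        s1 = {k: c.support for k, c in t1.bipartitions().items()}
        s2 = {k: c.support for k, c in t2.bipartitions().items()}
        assert s1 == s2

    def test_supports_lie_in_unit_interval(self):
        tree = bootstrap_supports(_quartet_alignment(), B=30, seed=3)
        for clade in tree.bipartitions(include_trivial=True).values():
            assert 0.0 <= clade.support <= 1.0


def _labelled_quartet(sa=0.87, sb=0.5):
    ca = Clade(support=sa, length=0.1,
               children=[Clade(name="a1", length=0.1), Clade(name="a2", length=0.1)])
    cb = Clade(support=sb, length=0.1,
               children=[Clade(name="b1", length=0.1), Clade(name="b2", length=0.1)])
    return UnrootedTree(
        Clade(children=[ca, cb, Clade(name="c1", length=0.2)])
    )


class TestMonophyly:
    def test_clustered_pair(self):
        tree = _labelled_quartet()
        ok, clade = is_monophyletic(tree, {"a1", "a2"})
        assert ok and clade.support == 0.87

    def test_interleaved_pair(self):
        tree = _labelled_quartet()
        ok, _ = is_monophyletic(tree, {"a1", "b1"})
        assert not ok

    def test_all_leaves_by_convention(self):
        tree = _labelled_quartet()
        ok, clade = is_monophyletic(tree, set(tree.leaf_names()))
        assert ok and clade is None

    def test_complement_symmetry(self):
        tree = _labelled_quartet()
        members = {"a1", "a2"}
        comp = set(tree.leaf_names()) - members
        assert is_monophyletic(tree, members)[0] == is_monophyletic(tree, comp)[0]

    def test_unknown_leaf_rejected(self):
        with pytest.raises(ValueError, match="zz"):
            is_monophyletic(_labelled_quartet(), {"zz"})


class TestTreeDiscrimination:
    RECORDS = [
        SampleRecord("a1", "A"), SampleRecord("a2", "A"),
        SampleRecord("b1", "B"), SampleRecord("b2", "B"),
        SampleRecord("c1", "C"),
    ]

    def _part(self):
        return make_partition(self.RECORDS, "species")

    def test_support_above_threshold_passes(self):
        decisions = tree_discriminate(_labelled_quartet(), self._part())
        by = {d.group_label: d for d in decisions}
        assert by["A"].discriminated

    def test_boundary_support_fails_strictly(self):
        decisions = tree_discriminate(_labelled_quartet(sb=0.5), self._part())
        by = {d.group_label: d for d in decisions}
        assert not by["B"].discriminated and by["B"].reason == "support_too_low"

    def test_singleton_excluded_from_rate(self):
        decisions = tree_discriminate(_labelled_quartet(), self._part())
        by = {d.group_label: d for d in decisions}
        assert by["C"].excluded
        assert discrimination_rate(decisions) == pytest.approx(50.0)

    def test_rate_non_increasing_in_threshold(self):
        rates = []
        for thr in (0.0, 0.4, 0.6, 0.9):
            decisions = tree_discriminate(
                _labelled_quartet(), self._part(), support_threshold=thr
            )
            rates.append(discrimination_rate(decisions))
        assert rates == sorted(rates, reverse=True)

    def test_partition_tree_mismatch_rejected(self):
        part = make_partition(self.RECORDS[:4], "species")
        with pytest.raises(ValueError, match="disagree"):
            tree_discriminate(_labelled_quartet(), part)
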