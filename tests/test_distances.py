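"""Pairwise comparisons, p/K2P distances, partitioning and gap histograms."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barcodegap.alignments import AlignedMatrix, SampleRecord, make_partition
from barcodegap.distances import (
    DistanceMatrix,
    PairwiseComparison,
    build_distance_matrix,
    compare_pair,
    gap_histogram,
    k2p_distance,
    p_distance,
    partition_distances,
)


class TestComparePair:
    def test_identical(self):
        c = compare_pair("ACGT", "ACGT")
        assert (c.n_compared, c.P, c.Q) == (4, 0.0, 0.0)

    def test_single_transition(self):
        c = compare_pair("AAAA", "GAAA")
        assert (c.n_transitions, c.n_transversions) == (1, 0)
        assert c.P == 0.25

    def test_pairwise_deletion(self):
        c = compare_pair("AC-T", "ACAT")
        assert c.n_compared == 3
        assert c.n_transitions + c.n_transversions == 0

    def test_ambiguity_excluded(self):
        c = compare_pair("ACRT", "ACGT")
        assert c.n_compared == 3

    def test_transversion_classification(self):
        c = compare_pair("AC", "CA")  # both purine<->pyrimidine
        assert (c.n_transitions, c.n_transversions) == (0, 2)

    def test_no_comparable_sites(self):
        c = compare_pair("--", "AC")
        assert not c.comparable
        assert math.isnan(p_distance(c))
        assert math.isnan(k2p_distance(c))


class TestDistances:
    def test_p_distance_examples(self):
        assert p_distance(compare_pair("AAAA", "AAAT")) == 0.25
        c = PairwiseComparison(100, 6, 4)
        assert p_distance(c) == pytest.approx(0.10)

    def test_k2p_closed_form_values(self):
        # P=0.1, Q=0.05 -> -1/2 ln(0.75) - 1/4 ln(0.90)
        assert k2p_distance(PairwiseComparison(100, 10, 5)) == pytest.approx(
            0.1701811651, abs=1e-9
        )
        # P=0.25, Q=0 -> -1/2 ln(0.5)
        assert k2p_distance(PairwiseComparison(100, 25, 0)) == pytest.approx(
            0.3465735903, abs=1e-9
        )
        assert k2p_distance(PairwiseComparison(100, 0, 0)) == 0.0

    def test_k2p_saturation_is_nan(self):
        assert math.isnan(k2p_distance(PairwiseComparison(100, 50, 0)))
        assert math.isnan(k2p_distance(PairwiseComparison(100, 0, 50)))

    @given(st.integers(0, 2**32 - 1))
    def test_k2p_dominates_p(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 300))
        ts = int(rng.integers(0, n // 3))
        tv = int(rng.integers(0, n // 4))
        c = PairwiseComparison(n, ts, tv)
        d_k2p = k2p_distance(c)
        d_p = p_distance(c)
        if not math.isnan(d_k2p):
            assert d_k2p >= d_p - 1e-15
            if d_p == 0:
                assert d_k2p == 0


class TestDistanceMatrix:
    def test_identical_rows(self):
        m = AlignedMatrix("m", ["a", "b"], ["ACGT", "ACGT"])
        dm = build_distance_matrix(m)
        assert np.allclose(dm.values, 0.0)

    def test_undefined_pair_flagged_not_zeroed(self):
        m = AlignedMatrix("m", ["a", "b", "c"], ["AC--", "--GT", "ACGT"])
        dm = build_distance_matrix(m, model="p")
        assert math.isnan(dm.value("a", "b"))
        assert dm.n_undefined_pairs == 1

    def test_self_concatenation_invariant(self, toy_matrix):
        from barcodegap.alignments import concatenate_markers

        single = build_distance_matrix(toy_matrix, model="k2p")
        doubled = build_distance_matrix(
            concatenate_markers([toy_matrix, toy_matrix]), model="k2p"
        )
        assert np.allclose(single.values, doubled.values)

    def test_row_permutation_equivariance(self, toy_matrix):
        perm = ["b2", "a1", "b1", "a2"]
        dm = build_distance_matrix(toy_matrix)
        dm_p = build_distance_matrix(toy_matrix.subset(perm))
        for i in toy_matrix.sample_ids:
            for j in toy_matrix.sample_ids:
                assert dm.value(i, j) == pytest.approx(dm_p.value(i, j))

    def test_complete_deletion_drops_gap_columns_for_all(self):
        m = AlignedMatrix("m", ["a", "b", "c"], ["ACGT", "AC-T", "GCGT"])
        pair = build_distance_matrix(m, model="p", deletion="pairwise")
        comp = build_distance_matrix(m, model="p", deletion="complete")
        assert pair.value("a", "c") == pytest.approx(1 / 4)
        assert comp.value("a", "c") == pytest.approx(1 / 3)

    def test_symmetry_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def _two_species_fixture():
    # within-pair distance 0.01, between 0.10 on 100 sites
    base = "A" * 100

    def mutate(s, k, to="G"):
        return s[:k] + to * 1 + s[k + 1:]

    a1 = base
    a2 = mutate(base, 0)  # 1 diff from a1
    b = "C" * 10 + "A" * 90  # 10 diffs from a1
    b1 = b
    b2 = mutate(b, 99)
    m = AlignedMatrix("m", ["a1", "a2", "b1", "b2"], [a1, a2, b1, b2])
    records = [
        SampleRecord("a1", "A"), SampleRecord("a2", "A"),
        SampleRecord("b1", "B"), SampleRecord("b2", "B"),
    ]
    part = make_partition(records, "species")
    return build_distance_matrix(m, model="p"), part


class TestPartitionDistances:
    def test_two_species_extremes_and_means(self):
        dm, part = _two_species_fixture()
        summaries, stats = partition_distances(dm, part)
        by = {s.group_label: s for s in summaries}
        assert by["A"].max_intra == pytest.approx(0.01)
        assert by["A"].min_inter == pytest.approx(0.10)
        assert stats.mean_intra == pytest.approx(0.01)
        assert stats.mean_inter > stats.mean_intra

    def test_all_identical(self):
        m = AlignedMatrix("m", ["a1", "a2", "b1"], ["ACGT"] * 3)
        records = [
            SampleRecord("a1", "A"), SampleRecord("a2", "A"), SampleRecord("b1", "B"),
        ]
        dm = build_distance_matrix(m)
        _, stats = partition_distances(dm, make_partition(records, "species"))
        assert stats.mean_intra == 0.0
        assert stats.mean_inter == 0.0

    def test_singleton_group(self):
        m = AlignedMatrix("m", ["a1", "a2", "b1"], ["ACGT", "ACGT", "AGGT"])
        records = [
            SampleRecord("a1", "A"), SampleRecord("a2", "A"), SampleRecord("b1", "B"),
        ]
        summaries, _ = partition_distances(
            build_distance_matrix(m), make_partition(records, "species")
        )
        by = {s.group_label: s for s in summaries}
        assert math.isnan(by["B"].max_intra)
        assert by["B"].min_inter > 0

    def test_missing_sample_named(self):
        dm, part = _two_species_fixture()
        smaller = make_partition(
            [SampleRecord("a1", "A"), SampleRecord("a2", "A"),
             SampleRecord("b1", "B"), SampleRecord("b2", "B")],
            "species", restrict_to=["a1", "a2", "b1"],
        )
        with pytest.raises(ValueError, match="b2"):
            partition_distances(dm, smaller)


class TestGapHistogram:
    def test_binning(self):
        dm, part = _two_species_fixture()
        hist = gap_histogram(dm, part, bin_width=0.01)
        frame = hist.to_frame()
        # intra distances {0.01, 0.01}; inter around 0.09-0.11
        assert frame.intra_count.sum() == 2
        assert frame.inter_count.sum() == 4

    def test_conservation_and_drop_tally(self):
        m = AlignedMatrix("m", ["a1", "a2", "b1"], ["AC--", "ACGT", "--GT"])
        records = [
            SampleRecord("a1", "A"), SampleRecord("a2", "A"), SampleRecord("b1", "B"),
        ]
        part = make_partition(records, "species")
        dm = build_distance_matrix(m, model="p")
        hist = gap_histogram(dm, part, bin_width=0.05)
        assert hist.n_dropped == 1  # a1-b1 has no comparable sites
        assert hist.intra_counts.sum() + hist.inter_counts.sum() == 2

    def test_empty_intra_series(self):
        m = AlignedMatrix("m", ["a1", "b1"], ["ACGT", "AGGT"])
        records = [SampleRecord("a1", "A"), SampleRecord("b1", "B")]
        hist = gap_histogram(
            build_distance_matrix(m), make_partition(records, "species"), 0.01
        )
        assert hist.intra_counts.sum() == 0
        assert hist.inter_counts.sum() == 1

    def test_bad_bin_width(self):
        dm, part = _two_species_fixture()
        with pytest.raises(ValueError):
            gap_histogram(dm, part, bin_width=0.0)
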