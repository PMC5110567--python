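"""Pairwise genetic distances and barcoding-gap summaries.

Two distance estimators are provided over the same site-counting machinery:

* uncorrected p-distance, ``p = (ts + tv) / n_compared``;
* Kimura two-parameter distance,
  ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``,
  with ``P`` the transition and ``Q`` the transversion proportion.

Sites are compared with *pairwise deletion*: a column counts for a pair only
when both rows carry an unambiguous nucleotide (A, C, G, T); gaps, N and
ambiguity codes are skipped for that pair alone.  ``deletion="complete"``
instead drops every column containing any non-ACGT character in any row.

Undefined distances (no comparable sites, or a saturated K2P logarithm) are
represented as NaN and are excluded — with a tally — from means, minima and
histograms; they are never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignments import AlignedMatrix, SpeciesPartition

__all__ = [
    "PairwiseComparison",
    "DistanceMatrix",
    "GroupDistanceSummary",
    "DatasetDistanceStats",
    "GapHistogram",
    "compare_pair",
    "p_distance",
    "k2p_distance",
    "PairTallies",
    "build_distance_matrix",
    "partition_distances",
    "gap_histogram",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, 255, dtype=np.uint8)
for _c, _v in zip(b"AGCT", (0, 1, 2, 3)):
    _CODE[_c] = _v


@dataclass(frozen=True)
class PairwiseComparison:
    """Site counts for one pair of aligned rows under pairwise deletion."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("differences exceed compared sites")

    @property
    def comparable(self) -> bool:
        return self.n_compared > 0

    @property
    def P(self) -> float:
        return self.n_transitions / self.n_compared

    @property
    def Q(self) -> float:
        return self.n_transversions / self.n_compared


def compare_pair(row_i: str, row_j: str) -> PairwiseComparison:
    """Count compared sites, transitions and transversions for two rows."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    a = _CODE[np.frombuffer(row_i.upper().encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_j.upper().encode("ascii"), dtype=np.uint8)]
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    ts = diff & ((a >> 1) == (b >> 1))
    return PairwiseComparison(
        n_compared=int(valid.sum()),
        n_transitions=int(ts.sum()),
        n_transversions=int(diff.sum() - ts.sum()),
    )


def p_distance(cmp: PairwiseComparison) -> float:
    """Uncorrected proportion of differing sites; NaN when no sites compare."""
    if not cmp.comparable:
        return float("nan")
    return (cmp.n_transitions + cmp.n_transversions) / cmp.n_compared


def k2p_distance(cmp: PairwiseComparison) -> float:
    """Kimura two-parameter distance; NaN when undefined or saturated."""
    if not cmp.comparable:
        return float("nan")
    w1 = 1.0 - 2.0 * cmp.P - cmp.Q
    w2 = 1.0 - 2.0 * cmp.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; NaN marks undefined entries."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {v.shape}")
        if not np.allclose(np.diagonal(v), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        defined = ~np.isnan(v)
        if not np.array_equal(defined, defined.T) or not np.allclose(
            v[defined & defined.T & ~np.eye(n, dtype=bool)],
            v.T[defined & defined.T & ~np.eye(n, dtype=bool)],
        ):
            raise ValueError("matrix must be symmetric")
        if np.any(v[defined] < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n_samples, 1)
        return int(np.isnan(self.values[iu]).sum())

    def value(self, i: str, j: str) -> float:
        a = self.sample_ids.index(i)
        b = self.sample_ids.index(j)
        return float(self.values[a, b])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


class PairTallies:
    """Per-column site classifications for all pairs, for fast re-weighting.

    For every unordered pair of rows and every alignment column this stores
    whether the column is comparable, a transition or a transversion.  A
    distance matrix under any column multiplicity vector (``None`` for the
    original alignment, a bootstrap resample's column counts otherwise) is
    then three matrix-vector products — this is what makes a 1000-replicate
    bootstrap cheap.
    """

    def __init__(self, matrix: AlignedMatrix, deletion: str = "pairwise"):
        if deletion not in ("pairwise", "complete"):
            raise ValueError(f"unknown deletion mode {deletion!r}")
        codes = matrix.codes()
        n, L = codes.shape
        if n < 2:
            raise ValueError("need at least two sequences")
        self.sample_ids = list(matrix.sample_ids)
        self.n = n
        self.n_columns = L
        self._iu = np.triu_indices(n, 1)
        ii, jj = self._iu
        a = codes[ii]  # (n_pairs, L)
        b = codes[jj]
        valid = (a < 4) & (b < 4)
        if deletion == "complete":
            keep = (codes < 4).all(axis=0)
            valid &= keep[None, :]
        diff = valid & (a != b)
        ts = diff & ((a >> 1) == (b >> 1))
        self._valid = valid.astype(np.float32)
        self._ts = ts.astype(np.float32)
        self._tv = (diff & ~ts).astype(np.float32)

    def counts(self, weights: np.ndarray | None = None):
        """(n_compared, n_ts, n_tv) square matrices under column weights."""
        if weights is None:
            nc = self._valid.sum(axis=1)
            nts = self._ts.sum(axis=1)
            ntv = self._tv.sum(axis=1)
        else:
            w = np.asarray(weights, dtype=np.float32)
            nc = self._valid @ w
            nts = self._ts @ w
            ntv = self._tv @ w
        out = []
        for flat in (nc, nts, ntv):
            m = np.zeros((self.n, self.n))
            m[self._iu] = flat
            out.append(m + m.T)
        return tuple(out)

    def distance_matrix(
        self, model: str = "k2p", weights: np.ndarray | None = None
    ) -> DistanceMatrix:
        nc, nts, ntv = self.counts(weights)
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == "p":
                d = (nts + ntv) / nc
            elif model == "k2p":
                P = nts / nc
                Q = ntv / nc
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
                d[(w1 <= 0) | (w2 <= 0)] = np.nan
            else:
                raise ValueError(f"unknown distance model {model!r}")
        d[nc == 0] = np.nan
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(sample_ids=list(self.sample_ids), values=d)


def build_distance_matrix(
    matrix: AlignedMatrix, model: str = "k2p", deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs distance matrix; undefined pairs are NaN, never zeroed."""
    if matrix.n_samples < 2:
        raise ValueError("need at least two sequences")
    dm = PairTallies(matrix, deletion=deletion).distance_matrix(model)
    if dm.n_undefined_pairs:
        logger.warning(
            "%s: %d undefined %s distance pair(s)",
            matrix.marker_name,
            dm.n_undefined_pairs,
            model,
        )
    return dm


@dataclass
class GroupDistanceSummary:
    """Per-group divergence extremes for the barcoding-gap criterion."""

    group_label: str
    n_members: int
    max_intra: float  # NaN for singletons or all-undefined intra pairs
    min_inter: float  # NaN when every interspecific pair is undefined


@dataclass
class DatasetDistanceStats:
    mean_intra: float
    mean_inter: float
    n_intra_pairs: int
    n_inter_pairs: int
    n_dropped_intra: int
    n_dropped_inter: int


def _pair_class_masks(dm: DistanceMatrix, part: SpeciesPartition):
    group_of = part.group_of()
    missing = [s for s in dm.sample_ids if s not in group_of]
    if missing:
        raise ValueError(f"samples missing from partition: {sorted(missing)}")
    labels = np.array([group_of[s] for s in dm.sample_ids])
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(dm.n_samples, 1)
    return labels, same, iu


def partition_distances(
    dm: DistanceMatrix, part: SpeciesPartition
) -> tuple[list[GroupDistanceSummary], DatasetDistanceStats]:
    """Split pairwise distances into intra- and inter-group sets.

    Returns per-group summaries (max intra-group and min inter-group
    distance; NaN where undefined) plus dataset-level means over all defined
    pairs.  Undefined (NaN) distances are dropped and tallied.
    """
    labels, same, iu = _pair_class_masks(dm, part)
    v = dm.values
    intra_vals = v[iu][same[iu]]
    inter_vals = v[iu][~same[iu]]

    def _mean(x):
        x = x[~np.isnan(x)]
        return float(x.mean()) if x.size else float("nan")

    stats = DatasetDistanceStats(
        mean_intra=_mean(intra_vals),
        mean_inter=_mean(inter_vals),
        n_intra_pairs=int(np.sum(~np.isnan(intra_vals))),
        n_inter_pairs=int(np.sum(~np.isnan(inter_vals))),
        n_dropped_intra=int(np.sum(np.isnan(intra_vals))),
        n_dropped_inter=int(np.sum(np.isnan(inter_vals))),
    )
    summaries = []
    index = {s: k for k, s in enumerate(dm.sample_ids)}
    for label in sorted(part.groups):
        members = sorted(part.groups[label])
        idx = np.array([index[m] for m in members])
        others = np.array([k for k in range(dm.n_samples) if k not in set(idx)])
        if len(idx) >= 2:
            block = v[np.ix_(idx, idx)]
            tri = block[np.triu_indices(len(idx), 1)]
            tri = tri[~np.isnan(tri)]
            max_intra = float(tri.max()) if tri.size else float("nan")
        else:
            max_intra = float("nan")
        if others.size:
            cross = v[np.ix_(idx, others)].ravel()
            cross = cross[~np.isnan(cross)]
            min_inter = float(cross.min()) if cross.size else float("nan")
        else:
            min_inter = float("nan")
        summaries.append(
            GroupDistanceSummary(
                group_label=label,
                n_members=len(members),
                max_intra=max_intra,
                min_inter=min_inter,
            )
        )
    return summaries, stats


@dataclass
class GapHistogram:
    """Binned intra vs inter distance frequencies (barcoding-gap plot data)."""

    bin_width: float
    intra_counts: np.ndarray
    inter_counts: np.ndarray
    n_dropped: int

    @property
    def n_bins(self) -> int:
        return max(len(self.intra_counts), len(self.inter_counts))

    def to_frame(self) -> pd.DataFrame:
        nb = self.n_bins
        intra = np.zeros(nb, dtype=int)
        inter = np.zeros(nb, dtype=int)
        intra[: len(self.intra_counts)] = self.intra_counts
        inter[: len(self.inter_counts)] = self.inter_counts
        return pd.DataFrame(
            {
                "bin_start": np.arange(nb) * self.bin_width,
                "intra_count": intra,
                "inter_count": inter,
            }
        )


def gap_histogram(
    dm: DistanceMatrix, part: SpeciesPartition, bin_width: float = 0.005
) -> GapHistogram:
    """Histogram intra- and inter-group distances in bins ``[k*w, (k+1)*w)``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    labels, same, iu = _pair_class_masks(dm, part)
    v = dm.values
    intra = v[iu][same[iu]]
    inter = v[iu][~same[iu]]
    dropped = int(np.isnan(intra).sum() + np.isnan(inter).sum())
    intra = intra[~np.isnan(intra)]
    inter = inter[~np.isnan(inter)]

    def _bin(x):
        if x.size == 0:
            return np.zeros(0, dtype=int)
        idx = np.floor(x / bin_width).astype(int)
        return np.bincount(idx)

    return GapHistogram(
        bin_width=bin_width,
        intra_counts=_bin(intra),
        inter_counts=_bin(inter),
        n_dropped=dropped,
    )
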