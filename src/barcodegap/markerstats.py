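"""Per-marker alignment statistics: variable sites (SNPs) and indel events.

A column is variable when at least two distinct *unambiguous* nucleotides
(A, C, G, T) occur in it; gaps, N and IUPAC ambiguity codes never contribute
to polymorphism.  An indel event is a maximal run of consecutive gap columns
within one row, identified by its column span; the same span appearing in
several rows (a deletion shared by a clade) is counted once — this mirrors
event-based indel counting rather than counting gap-bearing columns, which
is also available via ``mode="gap_columns"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .alignments import AlignedMatrix

__all__ = [
    "MarkerSummary",
    "count_variable_sites",
    "count_indel_events",
    "marker_summary",
]

_GAP_RUN = re.compile(r"-+")


def count_variable_sites(matrix: AlignedMatrix) -> int:
    """Number of columns with >= 2 distinct unambiguous nucleotides."""
    if matrix.n_samples < 2:
        raise ValueError("variable sites need at least two sequences")
    codes = matrix.codes()
    present = np.stack([(codes == b).any(axis=0) for b in range(4)])
    return int((present.sum(axis=0) >= 2).sum())


def count_indel_events(matrix: AlignedMatrix, mode: str = "events") -> int:
    """Count indels, either as deduplicated gap-run events or as gap columns."""
    if matrix.n_samples < 2:
        raise ValueError("indel counting needs at least two sequences")
    if mode == "gap_columns":
        codes = matrix.codes()
        raw = np.frombuffer(
            "".join(matrix.rows).encode("ascii"), dtype=np.uint8
        ).reshape(codes.shape)
        return int((raw == ord("-")).any(axis=0).sum())
    if mode != "events":
        raise ValueError(f"unknown indel mode {mode!r}")
    spans = {
        m.span() for row in matrix.rows for m in _GAP_RUN.finditer(row)
    }
    return len(spans)


@dataclass
class MarkerSummary:
    """One marker-evaluation row: alignment statistics, divergences and rates."""

    marker_name: str
    aligned_length: int
    n_snps: int
    n_indels: int
    mean_inter: float | None = None
    mean_intra: float | None = None
    rate_pwg: float | None = None
    rate_nj: float | None = None

    @property
    def pct_snp(self) -> float:
        return 100.0 * self.n_snps / self.aligned_length

    def __post_init__(self) -> None:
        if not 0 <= self.n_snps <= self.aligned_length:
            raise ValueError("n_snps must lie in [0, aligned_length]")
        for rate in (self.rate_pwg, self.rate_nj):
            if rate is not None and not 0.0 <= rate <= 100.0:
                raise ValueError(f"discrimination rate {rate} outside [0, 100]")


def marker_summary(
    matrix: AlignedMatrix,
    *,
    mean_inter: float | None = None,
    mean_intra: float | None = None,
    rate_pwg: float | None = None,
    rate_nj: float | None = None,
    indel_mode: str = "events",
) -> MarkerSummary:
    """Assemble the summary row for one marker or marker combination."""
    return MarkerSummary(
        marker_name=matrix.marker_name,
        aligned_length=matrix.n_columns,
        n_snps=count_variable_sites(matrix),
        n_indels=count_indel_events(matrix, mode=indel_mode),
        mean_inter=mean_inter,
        mean_intra=mean_intra,
        rate_pwg=rate_pwg,
        rate_nj=rate_nj,
    )
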