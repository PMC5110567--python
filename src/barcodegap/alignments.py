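"""Aligned sequence matrices, sample metadata and species/section partitions.

The in-memory workhorse is :class:`AlignedMatrix`: a labelled taxa x columns
character matrix for one marker (or a multi-marker concatenation).  Sequences
are stored uppercase with ``U`` mapped to ``T``; the alphabet is
``{A,C,G,T,N,-}`` plus IUPAC ambiguity codes.  Species and section labels come
only from the metadata table, never from FASTA headers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SampleRecord",
    "AlignedMatrix",
    "SpeciesPartition",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "make_partition",
    "concatenate_markers",
]

#: Characters accepted in an alignment row (uppercase, after U->T mapping).
ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")

# Numeric codes: A=0, G=1, C=2, T=3 (transition partner = code ^ 1,
# transversion partners = code ^ 2 and code ^ 3); everything else 255.
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _c, _v in zip(b"AGCT", (0, 1, 2, 3)):
    _CODE_TABLE[_c] = _v


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual: identity plus species/section/population labels."""

    sample_id: str
    species: str
    section: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.species:
            raise ValueError(f"species label missing for sample {self.sample_id!r}")


class AlignedMatrix:
    """Taxa x aligned-column character matrix with sample labels.

    Parameters
    ----------
    marker_name:
        Name of the marker (or ``"+"``-joined names for a concatenation).
    sample_ids:
        Ordered, distinct sample identifiers, one per row.
    rows:
        Equal-length uppercase sequence strings, one per sample.
    """

    def __init__(self, marker_name: str, sample_ids: Sequence[str], rows: Sequence[str]):
        sample_ids = list(sample_ids)
        rows = [str(r).upper().replace("U", "T") for r in rows]
        if len(sample_ids) != len(rows):
            raise ValueError("sample_ids and rows must have equal length")
        if not rows:
            raise ValueError(f"alignment {marker_name!r} is empty")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids in {marker_name!r}: {dupes}")
        ncol = len(rows[0])
        if ncol < 1:
            raise ValueError(f"alignment {marker_name!r} has zero columns")
        for sid, row in zip(sample_ids, rows):
            if len(row) != ncol:
                raise ValueError(
                    f"{marker_name!r} is not aligned: {sid!r} has length "
                    f"{len(row)}, expected {ncol}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in row {sid!r}")
        self.marker_name = marker_name
        self.sample_ids = sample_ids
        self.rows = rows
        self._codes: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """(n_samples, n_columns) uint8 array; A,G,C,T -> 0..3, other -> 255."""
        if self._codes is None:
            raw = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_samples, self.n_columns)
            self._codes = _CODE_TABLE[raw]
        return self._codes

    def row(self, sample_id: str) -> str:
        return self.rows[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "AlignedMatrix":
        """Restrict (and reorder) to the given sample ids."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from {self.marker_name!r}: {missing}")
        return AlignedMatrix(
            self.marker_name,
            list(sample_ids),
            [self.rows[index[s]] for s in sample_ids],
        )

    def take_columns(self, columns: Sequence[int]) -> "AlignedMatrix":
        """Column resample/subset (used by the alignment bootstrap)."""
        cols = np.asarray(columns, dtype=int)
        raw = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        raw = raw.reshape(self.n_samples, self.n_columns)[:, cols]
        rows = [bytes(r).decode("ascii") for r in raw]
        return AlignedMatrix(self.marker_name, list(self.sample_ids), rows)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AlignedMatrix)
            and self.marker_name == other.marker_name
            and self.sample_ids == other.sample_ids
            and self.rows == other.rows
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AlignedMatrix({self.marker_name!r}, {self.n_samples} samples x "
            f"{self.n_columns} columns)"
        )


@dataclass(frozen=True)
class SpeciesPartition:
    """Disjoint grouping of samples by species or by taxonomic section."""

    level: str
    groups: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if self.level not in ("species", "section"):
            raise ValueError(f"level must be 'species' or 'section', got {self.level!r}")
        object.__setattr__(
            self, "groups", {k: frozenset(v) for k, v in self.groups.items()}
        )
        seen: dict[str, str] = {}
        for label, members in self.groups.items():
            if not members:
                raise ValueError(f"group {label!r} is empty")
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"sample {m!r} appears in both {seen[m]!r} and {label!r}"
                    )
                seen[m] = label

    @property
    def sample_ids(self) -> frozenset:
        return frozenset().union(*self.groups.values())

    def group_of(self) -> dict[str, str]:
        """Mapping sample_id -> group label."""
        return {m: g for g, members in self.groups.items() for m in members}


# ----------------------------------------------------------------------
# File I/O


def read_alignment(path: str | Path, marker_name: str) -> AlignedMatrix:
    """Read one aligned FASTA file into an :class:`AlignedMatrix`.

    All records must have equal length (the file is an alignment, not raw
    reads); record ids become sample ids; sequences are uppercased and ``U``
    is mapped to ``T``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(
            f"{path}: not aligned (sequence lengths {sorted(lengths)})"
        )
    return AlignedMatrix(marker_name, ids, rows)


def write_alignment(matrix: AlignedMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(matrix.sample_ids, matrix.rows):
            fh.write(f">{sid}\n{row}\n")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV (sample_id, species, section, population).

    ``sample_id`` and ``species`` are required columns; ``section`` and
    ``population`` default to empty strings when absent.  Whitespace is
    trimmed; duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "species"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in ("section", "population"):
        if col not in df.columns:
            df[col] = ""
    records = []
    seen: set[str] = set()
    for _, r in df.iterrows():
        sid = r["sample_id"].strip()
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        records.append(
            SampleRecord(
                sample_id=sid,
                species=r["species"].strip(),
                section=r["section"].strip(),
                population=r["population"].strip(),
            )
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, sep="\t", index=False)


def make_partition(
    records: Sequence[SampleRecord],
    level: str,
    restrict_to: Iterable[str] | None = None,
) -> SpeciesPartition:
    """Group sample ids by species or section label.

    ``restrict_to`` limits the partition to a subset of samples (e.g. those
    present in a particular marker alignment); groups that lose all members
    are dropped.  Samples with an empty label at the requested level raise an
    error — callers should restrict to labelled samples first.
    """
    if level not in ("species", "section"):
        raise ValueError(f"level must be 'species' or 'section', got {level!r}")
    by_id = {r.sample_id: r for r in records}
    if restrict_to is None:
        wanted = list(by_id)
    else:
        wanted = list(restrict_to)
        missing = [s for s in wanted if s not in by_id]
        if missing:
            raise KeyError(f"sample ids absent from metadata: {sorted(missing)}")
    groups: dict[str, set] = {}
    for sid in wanted:
        label = getattr(by_id[sid], level)
        if not label:
            raise ValueError(f"sample {sid!r} has no {level} label")
        groups.setdefault(label, set()).add(sid)
    return SpeciesPartition(level=level, groups=groups)


def concatenate_markers(
    matrices: Sequence[AlignedMatrix], mode: str = "intersection"
) -> AlignedMatrix:
    """Column-wise concatenation over the samples shared by every marker.

    Strict intersection: a sample missing from any input marker is dropped
    (no missing-data padding), so combined datasets shrink to shared taxa.
    Sample order follows the first matrix.
    """
    if mode != "intersection":
        raise ValueError(f"unsupported concatenation mode {mode!r}")
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to concatenate")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if not shared:
        names = [m.marker_name for m in matrices]
        raise ValueError(f"no samples shared by all of {names}")
    order = [s for s in matrices[0].sample_ids if s in shared]
    parts = [m.subset(order) for m in matrices]
    rows = ["".join(p.rows[i] for p in parts) for i in range(len(order))]
    name = "+".join(m.marker_name for m in matrices)
    return AlignedMatrix(name, order, rows)
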