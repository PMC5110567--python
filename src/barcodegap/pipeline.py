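"""Orchestration: evaluate every marker and marker combination, write reports.

For each evaluation unit (a single marker, or the intersection-concatenation
of several) the pipeline computes alignment statistics, distance matrices,
the gap histogram, the pairwise-gap criterion decisions and rate, and the
bootstrap NJ tree with the monophyly criterion decisions and rate — at the
species level and, when section labels are present, at the section level.

Distance-model conventions follow common barcoding practice: summary
divergences, histograms and trees use the K2P model; the gap criterion
defaults to the uncorrected p-distance (configurable).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignments import (
    AlignedMatrix,
    concatenate_markers,
    make_partition,
    read_alignment,
    read_metadata,
)
from .distances import (
    DatasetDistanceStats,
    GapHistogram,
    build_distance_matrix,
    gap_histogram,
    partition_distances,
)
from .markerstats import MarkerSummary, marker_summary
from .njtree import TreeDecision, evaluate_tree
from .pwg import GroupDecision, discrimination_rate, pwg_decide
from .trees import UnrootedTree, write_newick

__all__ = [
    "EvaluationConfig",
    "LevelResult",
    "UnitResult",
    "DiscriminationReport",
    "run_evaluation",
    "render_reports",
    "default_combinations",
    "unit_label",
]

logger = logging.getLogger(__name__)

#: Conventional one-letter abbreviations for the four classical markers.
MARKER_LETTERS = {"rbcL": "R", "matK": "M", "trnS-trnG": "T", "ITS": "I"}


def default_combinations() -> list[list[str]]:
    """The eight classical multi-locus combinations of R, M, T and I."""
    return [
        ["rbcL", "matK"],
        ["matK", "trnS-trnG"],
        ["rbcL", "trnS-trnG"],
        ["trnS-trnG", "ITS"],
        ["rbcL", "ITS"],
        ["matK", "ITS"],
        ["rbcL", "matK", "trnS-trnG"],
        ["rbcL", "matK", "trnS-trnG", "ITS"],
    ]


def unit_label(markers: list[str]) -> str:
    """Short display label, e.g. ['rbcL', 'ITS'] -> 'R+I'."""
    if all(m in MARKER_LETTERS for m in markers):
        return "+".join(MARKER_LETTERS[m] for m in markers)
    return "+".join(markers)


@dataclass
class EvaluationConfig:
    """Full experiment grid and knobs for one evaluation run."""

    marker_files: dict  # marker name -> aligned FASTA path
    metadata_file: str
    combinations: list = field(default_factory=list)  # list of marker-name lists
    pwg_model: str = "p"
    table_model: str = "k2p"
    deletion: str = "pairwise"
    bootstrap_replicates: int = 1000
    support_threshold: float = 0.5
    singleton_policy: str = "exclude"
    bin_width: float = 0.005
    indel_mode: str = "events"
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if not self.marker_files:
            raise ValueError("no marker files configured")
        for combo in self.combinations:
            unknown = [m for m in combo if m not in self.marker_files]
            if unknown:
                raise ValueError(f"combination {combo} references unknown markers {unknown}")
            if len(combo) < 2:
                raise ValueError(f"combination {combo} needs >= 2 markers")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvaluationConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class LevelResult:
    """Both criteria evaluated for one grouping level (species or section)."""

    level: str
    n_groups: int
    pwg_decisions: list
    pwg_rate: float
    tree_decisions: list
    tree_rate: float


@dataclass
class UnitResult:
    """Everything computed for one marker or combination."""

    label: str
    markers: list
    n_samples: int
    summary: MarkerSummary
    dataset_stats: DatasetDistanceStats
    histogram: GapHistogram
    tree: UnrootedTree
    levels: dict  # level name -> LevelResult


@dataclass
class DiscriminationReport:
    config: EvaluationConfig
    units: dict  # label -> UnitResult
    failures: dict  # label -> error message

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for label, u in self.units.items():
            s = u.summary
            species = u.levels.get("species")
            section = u.levels.get("section")
            rows.append(
                {
                    "region": label,
                    "n_samples": u.n_samples,
                    "n_species": species.n_groups if species else 0,
                    "aligned_length": s.aligned_length,
                    "n_snps": s.n_snps,
                    "pct_snp": round(s.pct_snp, 2),
                    "n_indels": s.n_indels,
                    "mean_inter": round(u.dataset_stats.mean_inter, 4),
                    "mean_intra": round(u.dataset_stats.mean_intra, 4),
                    "rate_pwg": round(species.pwg_rate, 2) if species else np.nan,
                    "rate_nj": round(species.tree_rate, 2) if species else np.nan,
                    "rate_pwg_section": round(section.pwg_rate, 2) if section else np.nan,
                    "rate_nj_section": round(section.tree_rate, 2) if section else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _unit_seed(base_seed: int, label: str) -> np.random.SeedSequence:
    """Stable per-unit seed: run seed + CRC of the unit label."""
    return np.random.SeedSequence([base_seed, zlib.crc32(label.encode()) & 0x7FFFFFFF])


def _evaluate_level(
    matrix: AlignedMatrix,
    records: list,
    level: str,
    dm_pwg,
    tree: UnrootedTree,
    cfg: EvaluationConfig,
) -> LevelResult | None:
    by_id = {r.sample_id: r for r in records}
    labelled = [s for s in matrix.sample_ids if getattr(by_id[s], level)]
    if not labelled:
        return None
    if len(labelled) < len(matrix.sample_ids):
        logger.info(
            "%s: %d samples lack a %s label; excluded at this level",
            matrix.marker_name, len(matrix.sample_ids) - len(labelled), level,
        )
        if level == "section":
            # the tree contains all samples; section monophyly is only
            # testable when every leaf carries a section label
            return None
    part = make_partition(records, level, restrict_to=labelled)
    summaries, _ = partition_distances(dm_pwg, part)
    pwg_decisions = [pwg_decide(s, cfg.singleton_policy) for s in summaries]
    pwg_rate = discrimination_rate(pwg_decisions)
    from .njtree import tree_discriminate

    tree_decisions = tree_discriminate(
        tree, part,
        support_threshold=cfg.support_threshold,
        singleton_policy=cfg.singleton_policy,
    )
    tree_rate = discrimination_rate(tree_decisions)
    return LevelResult(
        level=level,
        n_groups=len(part.groups),
        pwg_decisions=pwg_decisions,
        pwg_rate=pwg_rate,
        tree_decisions=tree_decisions,
        tree_rate=tree_rate,
    )


def _evaluate_unit(
    markers: list,
    matrices: dict,
    records: list,
    cfg: EvaluationConfig,
) -> UnitResult:
    label = unit_label(markers)
    if len(markers) == 1:
        matrix = matrices[markers[0]]
    else:
        matrix = concatenate_markers([matrices[m] for m in markers])
    ids = set(matrix.sample_ids)
    part = make_partition(records, "species", restrict_to=matrix.sample_ids)

    dm_table = build_distance_matrix(matrix, model=cfg.table_model, deletion=cfg.deletion)
    if cfg.pwg_model == cfg.table_model:
        dm_pwg = dm_table
    else:
        dm_pwg = build_distance_matrix(matrix, model=cfg.pwg_model, deletion=cfg.deletion)

    _, dataset_stats = partition_distances(dm_table, part)
    hist = gap_histogram(dm_table, part, bin_width=cfg.bin_width)

    tree, _, _ = evaluate_tree(
        matrix,
        part,
        model=cfg.table_model,
        B=cfg.bootstrap_replicates,
        seed=_unit_seed(cfg.seed, label),
        support_threshold=cfg.support_threshold,
        singleton_policy=cfg.singleton_policy,
        deletion=cfg.deletion,
    )

    levels = {}
    for level in ("species", "section"):
        res = _evaluate_level(matrix, records, level, dm_pwg, tree, cfg)
        if res is not None:
            levels[level] = res

    summary = marker_summary(
        matrix,
        mean_inter=dataset_stats.mean_inter,
        mean_intra=dataset_stats.mean_intra,
        rate_pwg=levels["species"].pwg_rate if "species" in levels else None,
        rate_nj=levels["species"].tree_rate if "species" in levels else None,
        indel_mode=cfg.indel_mode,
    )
    return UnitResult(
        label=label,
        markers=list(markers),
        n_samples=matrix.n_samples,
        summary=summary,
        dataset_stats=dataset_stats,
        histogram=hist,
        tree=tree,
        levels=levels,
    )


def run_evaluation(
    cfg: EvaluationConfig, matrices: dict | None = None, records: list | None = None
) -> DiscriminationReport:
    """Run the full grid; in-memory inputs may be passed to skip file reads."""
    cfg.validate()
    if matrices is None:
        matrices = {
            name: read_alignment(path, name) for name, path in cfg.marker_files.items()
        }
    if records is None:
        records = read_metadata(cfg.metadata_file)

    units: dict = {}
    failures: dict = {}
    grid = [[m] for m in matrices] + [list(c) for c in cfg.combinations]
    for markers in grid:
        label = unit_label(markers)
        try:
            units[label] = _evaluate_unit(markers, matrices, records, cfg)
        except Exception as exc:  # keep other units alive; report the hole
            logger.error("unit %s failed: %s", label, exc)
            failures[label] = str(exc)
    report = DiscriminationReport(config=cfg, units=units, failures=failures)
    if cfg.output_dir:
        render_reports(report, cfg.output_dir)
    return report


# ----------------------------------------------------------------------
# Report rendering


def _decisions_frame(decisions: list) -> pd.DataFrame:
    rows = []
    for d in decisions:
        row = {"group": d.group_label, "n": d.n_members}
        if isinstance(d, GroupDecision):
            row.update(
                max_intra=round(d.max_intra, 6) if not np.isnan(d.max_intra) else "",
                min_inter=round(d.min_inter, 6) if not np.isnan(d.min_inter) else "",
            )
        elif isinstance(d, TreeDecision):
            row.update(
                monophyletic=d.monophyletic,
                support=round(d.support, 4) if not np.isnan(d.support) else "",
            )
        row.update(discriminated=d.discriminated, reason=d.reason)
        rows.append(row)
    return pd.DataFrame(rows)


def render_reports(report: DiscriminationReport, outdir: str | Path) -> list[Path]:
    """Write summary/decision/histogram TSVs, newick trees and the run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)
    written: list[Path] = []

    def _safe(label: str) -> str:
        return label.replace("/", "_")

    path = outdir / "summary.tsv"
    report.summary_frame().to_csv(path, sep="\t", index=False)
    written.append(path)

    for label, u in report.units.items():
        stem = _safe(label)
        for level, res in u.levels.items():
            p = outdir / f"{stem}.pwg.{level}.tsv"
            _decisions_frame(res.pwg_decisions).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = outdir / f"{stem}.tree.{level}.tsv"
            _decisions_frame(res.tree_decisions).to_csv(p, sep="\t", index=False)
            written.append(p)
        p = outdir / f"{stem}.hist.tsv"
        u.histogram.to_frame().to_csv(p, sep="\t", index=False)
        written.append(p)
        p = outdir / "trees" / f"{stem}.nwk"
        write_newick(u.tree, p)
        written.append(p)

    log = {
        "version": __version__,
        "numpy": np.__version__,
        "config": dataclasses.asdict(report.config),
        "failures": report.failures,
        "undefined_pairs": {
            label: u.dataset_stats.n_dropped_intra + u.dataset_stats.n_dropped_inter
            for label, u in report.units.items()
        },
        "bootstrap_skipped": {
            label: getattr(u.tree, "bootstrap_skipped", 0)
            for label, u in report.units.items()
        },
    }
    p = outdir / "run_log.json"
    p.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
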