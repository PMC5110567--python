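"""Synthetic barcoding datasets with known ground truth.

The generator emulates the statistical structure of a multi-marker barcoding
study: a set of species related by a pure-birth (Yule) tree, a handful of
conspecific individuals per species hanging as a shallow star below each
species tip, and several markers evolving on the same genealogy at different
relative rates (a slow coding marker through a fast nuclear spacer), under
the Kimura two-parameter substitution process with transition/transversion
ratio ``kappa``.  Inter- and intra-specific depths are expected
substitutions per site at the reference (fastest) marker rate.

Because the gap criterion is only guaranteed when every pair of species is
separated by more than the intraspecific depth, the species tree enforces a
minimum recency for the shallowest split: terminal branches are extended so
the most recent speciation lies at least ``min_split_frac`` of the tree
height before the present, then the whole tree is rescaled to height
``interspecific_depth / 2``.  Set ``min_split_frac=0`` for an unconstrained
Yule tree.

Indels are inserted post hoc as gap spans shared by all individuals of a
randomly chosen species; spans are placed without overlap or adjacency, so
the event count recovered by indel counting equals the configured truth.

Everything is deterministic given the seed; identical configurations write
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignments import (
    AlignedMatrix,
    SampleRecord,
    write_alignment,
    write_metadata,
)
from .trees import Clade, UnrootedTree, to_newick

__all__ = [
    "MarkerSpec",
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_species_tree",
    "evolve_alignment",
    "simulate_dataset",
]


@dataclass(frozen=True)
class MarkerSpec:
    """One simulated marker: name, aligned length, relative rate, indel truth."""

    name: str
    length: int
    rate: float
    n_indels: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"marker {self.name!r}: length must be >= 1")
        if self.rate < 0:
            raise ValueError(f"marker {self.name!r}: rate must be >= 0")
        if self.n_indels < 0:
            raise ValueError(f"marker {self.name!r}: n_indels must be >= 0")


def default_markers() -> list[MarkerSpec]:
    """Four-marker ladder: two slow coding loci, a mid-rate chloroplast
    spacer rich in indels, and a fast nuclear spacer."""
    return [
        MarkerSpec("rbcL", 497, 0.09, 0),
        MarkerSpec("matK", 636, 0.18, 1),
        MarkerSpec("trnS-trnG", 366, 0.57, 44),
        MarkerSpec("ITS", 346, 1.00, 21),
    ]


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    ``interspecific_depth`` is the expected between-species divergence at the
    root (substitutions/site at relative rate 1); ``intraspecific_depth`` the
    expected divergence between two conspecific individuals.
    """

    n_species: int = 21
    individuals_per_species: tuple[int, int] = (2, 5)
    markers: list[MarkerSpec] = field(default_factory=default_markers)
    interspecific_depth: float = 0.05
    intraspecific_depth: float = 0.002
    kappa: float = 2.0
    min_split_frac: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        lo, hi = self.individuals_per_species
        if not 1 <= lo <= hi:
            raise ValueError("individuals_per_species must be a range 1 <= lo <= hi")
        if not self.markers:
            raise ValueError("need at least one marker")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.interspecific_depth < 0 or self.intraspecific_depth < 0:
            raise ValueError("depths must be non-negative")
        if not 0.0 <= self.min_split_frac < 1.0:
            raise ValueError("min_split_frac must lie in [0, 1)")
        for m in self.markers:
            dataclasses.asdict(m)  # triggers field validation on reconstruction

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SimulationTruth:
    """Ground truth shipped with a simulated dataset."""

    species_tree_newick: str
    assignments: dict  # sample_id -> species
    expected_divergence: dict  # marker -> {(sp_a, sp_b): expected subs/site}


@dataclass
class SimulatedDataset:
    matrices: dict  # marker name -> AlignedMatrix
    records: list
    truth: SimulationTruth
    config: SimulationConfig


# ----------------------------------------------------------------------


def simulate_species_tree(
    n_species: int,
    interspecific_depth: float,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    min_split_frac: float = 0.2,
    names: list[str] | None = None,
) -> Clade:
    """Ultrametric pure-birth species tree rescaled to height ``depth/2``.

    Returns the rooted tree (root at depth 0, all tips at
    ``interspecific_depth / 2``), so the expected divergence of two species
    meeting at the root is ``interspecific_depth``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if names is None:
        width = len(str(n_species))
        names = [f"sp{k + 1:0{width}d}" for k in range(n_species)]
    elif len(names) != n_species:
        raise ValueError("need one name per species")

    # forward simulation: split a random active lineage at each birth event
    root = Clade()
    left, right = Clade(), Clade()
    root.children = [left, right]
    birth: dict[int, float] = {id(left): 0.0, id(right): 0.0}
    active: list[Clade] = [left, right]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active[k]
        node.length = t - birth[id(node)]
        a, b = Clade(), Clade()
        node.children = [a, b]
        birth[id(a)] = birth[id(b)] = t
        active[k] = a
        active.append(b)
    t += rng.exponential(1.0 / n_species)  # stem from last split to the present
    for node in active:
        node.length = t - birth[id(node)]

    # enforce a floor on the recency of the shallowest split, then rescale
    if min_split_frac > 0:
        shallowest = min(node.length for node in active)
        need = (min_split_frac * t - shallowest) / (1.0 - min_split_frac)
        if need > 0:
            for node in active:
                node.length += need
            t += need
    scale = (interspecific_depth / 2.0) / t if t > 0 else 0.0
    for node in root.iter_postorder():
        node.length *= scale
    for name, node in zip(names, active):
        node.name = name
    return root


_TS_PARTNER = np.array([1, 0, 3, 2], dtype=np.uint8)  # A<->G, C<->T via code^1


def _k2p_event_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after branch length t (subs/site)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def _evolve_branch(
    seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if t <= 0:
        return seq.copy()
    p_ts, p_tv = _k2p_event_probs(t, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] = seq[ts] ^ 1
    out[tv1] = seq[tv1] ^ 2
    out[tv2] = seq[tv2] ^ 3
    return out


_BASES = np.frombuffer(b"AGCT", dtype=np.uint8)


def evolve_alignment(
    tree: Clade,
    length: int,
    kappa: float = 2.0,
    rate: float = 1.0,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    marker_name: str = "sim",
) -> AlignedMatrix:
    """Simulate sequences for every leaf of ``tree`` under the K2P process.

    Branch lengths are multiplied by ``rate`` before use; the root sequence
    is uniform over {A, C, G, T}; sites evolve independently.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)
    ids: list[str] = []
    rows: list[str] = []

    def _descend(node: Clade, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve_branch(seq, child.length * rate, kappa, rng)
            if child.is_leaf:
                ids.append(child.name)
                rows.append(bytes(_BASES[child_seq]).decode("ascii"))
            else:
                _descend(child, child_seq)

    _descend(tree, root_seq)
    return AlignedMatrix(marker_name, ids, rows)


def _place_gap_spans(
    rng: np.random.Generator, length: int, n_events: int, max_len: int = 6
) -> list[tuple[int, int]]:
    """Non-overlapping, non-adjacent half-open column spans for gap events."""
    if n_events == 0:
        return []
    lens = rng.integers(1, max_len + 1, size=n_events)
    needed = int(lens.sum()) + (n_events - 1)  # 1-column separators
    free = length - needed
    if free < 0:
        raise ValueError(
            f"cannot place {n_events} indel events in {length} columns"
        )
    # distribute the free columns as random gaps before/between/after spans
    cuts = np.sort(rng.integers(0, free + 1, size=n_events))
    spans = []
    pos = 0
    prev_cut = 0
    for k in range(n_events):
        pos += int(cuts[k] - prev_cut)
        prev_cut = int(cuts[k])
        start = pos
        pos += int(lens[k])
        spans.append((start, pos))
        pos += 1  # separator
    return spans


def _species_pair_divergence(root: Clade) -> dict:
    """Expected divergence (sum of path lengths to the MRCA) per species pair."""
    pairs: dict[tuple[str, str], float] = {}

    def _walk(node: Clade, depth: float) -> list[tuple[str, float]]:
        depth += node.length
        if node.is_leaf:
            return [(node.name, depth)]
        lists = [_walk(ch, depth) for ch in node.children]
        for x in range(len(lists)):
            for y in range(x + 1, len(lists)):
                for na, da in lists[x]:
                    for nb, db in lists[y]:
                        key = tuple(sorted((na, nb)))
                        pairs[key] = (da - depth) + (db - depth)
        return [item for sub in lists for item in sub]

    _walk(root, -root.length)
    return pairs


def simulate_dataset(
    cfg: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedDataset:
    """Generate a full multi-marker dataset (+ ground truth), optionally on disk.

    Written layout: one aligned FASTA per marker (``<name>.fasta``),
    ``metadata.tsv``, ``species_tree.nwk`` and ``config.json``; all readable
    back by the alignment readers unchanged.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    n_streams = 2 + 2 * len(cfg.markers)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_streams)]
    rng_tree, rng_ind = streams[0], streams[1]

    species_root = simulate_species_tree(
        cfg.n_species,
        cfg.interspecific_depth,
        seed=rng_tree,
        min_split_frac=cfg.min_split_frac,
    )
    species_names = [c.name for c in species_root.iter_postorder() if c.is_leaf]

    # attach individuals as a star of depth intra/2 below each species tip
    lo, hi = cfg.individuals_per_species
    records: list[SampleRecord] = []
    assignments: dict[str, str] = {}
    for tip in list(species_root.iter_postorder()):
        if not tip.is_leaf:
            continue
        sp = tip.name
        k = int(rng_ind.integers(lo, hi + 1))
        children = []
        for idx in range(k):
            sid = f"{sp}_i{idx + 1}"
            children.append(
                Clade(name=sid, length=cfg.intraspecific_depth / 2.0)
            )
            records.append(
                SampleRecord(sample_id=sid, species=sp, section="", population="p1")
            )
            assignments[sid] = sp
        tip.children = children
        tip.name = None

    matrices: dict[str, AlignedMatrix] = {}
    for m_idx, marker in enumerate(cfg.markers):
        rng_seq = streams[2 + 2 * m_idx]
        rng_indel = streams[3 + 2 * m_idx]
        mat = evolve_alignment(
            species_root,
            marker.length,
            kappa=cfg.kappa,
            rate=marker.rate,
            seed=rng_seq,
            marker_name=marker.name,
        )
        if marker.n_indels:
            spans = _place_gap_spans(rng_indel, marker.length, marker.n_indels)
            rows = [list(r) for r in mat.rows]
            row_index = {s: i for i, s in enumerate(mat.sample_ids)}
            for span in spans:
                sp = species_names[int(rng_indel.integers(len(species_names)))]
                for sid, owner in assignments.items():
                    if owner == sp:
                        i = row_index[sid]
                        for col in range(span[0], span[1]):
                            rows[i][col] = "-"
            mat = AlignedMatrix(
                marker.name, list(mat.sample_ids), ["".join(r) for r in rows]
            )
        matrices[marker.name] = mat

    # species-level truth tree (re-derive a clean copy for serialisation)
    truth_pairs = {
        m.name: {
            pair: d * m.rate
            for pair, d in _species_pair_divergence_species(cfg, species_root).items()
        }
        for m in cfg.markers
    }
    truth = SimulationTruth(
        species_tree_newick=_species_newick(species_root, assignments),
        assignments=assignments,
        expected_divergence=truth_pairs,
    )
    dataset = SimulatedDataset(
        matrices=matrices, records=records, truth=truth, config=cfg
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, mat in matrices.items():
            write_alignment(mat, outdir / f"{name}.fasta")
        write_metadata(records, outdir / "metadata.tsv")
        (outdir / "species_tree.nwk").write_text(truth.species_tree_newick + "\n")
        (outdir / "config.json").write_text(cfg.to_json() + "\n")
    return dataset


def _species_newick(individual_root: Clade, assignments: dict) -> str:
    """Newick of the species-level tree (individual stars collapsed back)."""
    import copy

    root = copy.deepcopy(individual_root)
    for node in root.iter_postorder():
        if node.children and all(ch.is_leaf for ch in node.children):
            species = {assignments.get(ch.name) for ch in node.children}
            if len(species) == 1 and None not in species:
                node.name = species.pop()
                node.children = []
    return to_newick(UnrootedTree(root), with_supports=False)


def _species_pair_divergence_species(cfg: SimulationConfig, root: Clade) -> dict:
    """Pairwise expected species divergences from the (individual-bearing) tree."""
    # collapse individuals: measure species tip depth at the star root
    pairs = _species_pair_divergence(root)
    out: dict[tuple[str, str], float] = {}
    seen_species: dict[tuple[str, str], float] = {}
    # individual-level pairs carry species labels via the naming scheme
    for (a, b), d in pairs.items():
        sa, sb = a.rsplit("_i", 1)[0], b.rsplit("_i", 1)[0]
        if sa == sb:
            continue
        key = tuple(sorted((sa, sb)))
        # all cross pairs share the same species path + 2 * intra/2
        seen_species.setdefault(key, d - cfg.intraspecific_depth)
    out.update(seen_species)
    return out
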