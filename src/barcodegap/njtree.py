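"""Neighbor-joining, the column bootstrap, and tree-based discrimination.

``nj_construct`` is the standard Saitou–Nei agglomeration: at each step join
the pair minimising ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` with
``r_i = sum_k d(i,k)``, branch lengths from the usual split formula.  Ties in
Q are broken by the lexicographically smallest ``(i, j)`` index pair in the
current matrix, which — together with seeded resampling — makes full runs
reproducible bit for bit.  On an additive matrix the generating topology and
branch lengths are recovered exactly; negative branch lengths are kept as
computed (a display-time clamp is available in the newick writer).

Bootstrap supports resample alignment *columns* with replacement, rebuild
the distance matrix and NJ tree per replicate, and score each internal edge
of the reference tree by the fraction of replicate trees containing the same
bipartition.  Replicates whose resampled matrix has undefined distances are
skipped and tallied.

A group is *discriminated* on the tree when it is monophyletic (one side of
some bipartition of the unrooted tree equals the group) and the supporting
edge's bootstrap support strictly exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignments import AlignedMatrix, SpeciesPartition
from .distances import DistanceMatrix, PairTallies
from .pwg import SINGLETON_POLICIES, discrimination_rate
from .trees import Clade, UnrootedTree, bipartition_key

__all__ = [
    "nj_construct",
    "bootstrap_supports",
    "is_monophyletic",
    "TreeDecision",
    "tree_discriminate",
    "evaluate_tree",
]

logger = logging.getLogger(__name__)


def nj_construct(dm: DistanceMatrix) -> UnrootedTree:
    """Neighbor-joining tree from a fully defined distance matrix."""
    n = dm.n_samples
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 samples")
    if np.isnan(dm.values).any():
        raise ValueError(
            "distance matrix has undefined entries; impute or drop the "
            "affected samples before tree building"
        )
    D = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=s) for s in dm.sample_ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        # upper triangle only; row-major argmin = lexicographic tie-break
        Q[np.tril_indices(m)] = np.inf
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        d_ij = D[i, j]
        vi = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d_ij - vi
        nodes[i].length = vi
        nodes[j].length = vj
        parent = Clade(children=[nodes[i], nodes[j]])
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep][None, :]])
        last = np.append(d_new[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    return UnrootedTree(Clade(children=[a, b, c]))


def bootstrap_supports(
    matrix: AlignedMatrix,
    model: str = "k2p",
    B: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    deletion: str = "pairwise",
) -> UnrootedTree:
    """Reference NJ tree with column-bootstrap supports on internal edges.

    Terminal edges are assigned support 1.0 (every tree contains every
    trivial bipartition).  The number of replicates skipped because of
    undefined resampled distances is recorded on the returned tree as
    ``tree.bootstrap_skipped``; supports are fractions of the effective
    (non-skipped) replicate count.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    tallies = PairTallies(matrix, deletion=deletion)
    reference = nj_construct(tallies.distance_matrix(model))
    ref_parts = reference.bipartitions(include_trivial=False)
    counts = {key: 0 for key in ref_parts}
    rng = np.random.default_rng(seed)
    L = matrix.n_columns
    skipped = 0
    for _ in range(B):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L)
        dm_b = tallies.distance_matrix(model, weights=w)
        if np.isnan(dm_b.values).any():
            skipped += 1
            continue
        for key in nj_construct(dm_b).bipartition_keys():
            if key in counts:
                counts[key] += 1
    effective = B - skipped
    if effective == 0:
        raise RuntimeError("all bootstrap replicates had undefined distances")
    if skipped:
        logger.warning("bootstrap: skipped %d/%d replicates", skipped, B)
    for key, clade in ref_parts.items():
        clade.support = counts[key] / effective
    leafsets = reference.leafsets()
    universe = frozenset(reference.leaf_names())
    for clade in reference.root.iter_postorder():
        if clade is reference.root or clade.support is not None:
            continue
        below = leafsets[id(clade)]
        if min(len(below), len(universe - below)) < 2:
            clade.support = 1.0
    reference.bootstrap_skipped = skipped
    reference.bootstrap_replicates = effective
    return reference


def is_monophyletic(
    tree: UnrootedTree, members: Iterable[str]
) -> tuple[bool, Clade | None]:
    """Unrooted monophyly: is ``members`` one side of some edge's bipartition?

    Returns ``(True, supporting_clade)`` when an edge separates exactly the
    members from everything else; a single member is trivially monophyletic
    (its terminal edge supports it); the full leaf set is monophyletic by
    convention with no supporting edge.
    """
    members = frozenset(members)
    universe = frozenset(tree.leaf_names())
    stray = members - universe
    if stray:
        raise ValueError(f"not leaves of the tree: {sorted(stray)}")
    if not members:
        raise ValueError("empty member set")
    if members == universe:
        return True, None
    key = bipartition_key(members, universe)
    clade = tree.bipartitions(include_trivial=True).get(key)
    return (clade is not None), clade


@dataclass
class TreeDecision:
    """Outcome of the monophyly-plus-support criterion for one group."""

    group_label: str
    n_members: int
    monophyletic: bool
    support: float  # NaN when not monophyletic or no supporting edge
    discriminated: bool
    reason: str  # monophyletic_supported | support_too_low | not_monophyletic |
    #              singleton_excluded | no_supporting_edge

    @property
    def excluded(self) -> bool:
        return self.reason == "singleton_excluded"


def tree_discriminate(
    tree: UnrootedTree,
    part: SpeciesPartition,
    support_threshold: float = 0.5,
    singleton_policy: str = "exclude",
) -> list[TreeDecision]:
    """Per-group tree-based decisions (monophyly and support > threshold)."""
    if not 0.0 <= support_threshold <= 1.0:
        raise ValueError("support_threshold must lie in [0, 1]")
    if singleton_policy not in SINGLETON_POLICIES:
        raise ValueError(f"unknown singleton_policy {singleton_policy!r}")
    leaves = set(tree.leaf_names())
    part_samples = part.sample_ids
    if part_samples != frozenset(leaves):
        raise ValueError(
            "partition and tree leaves disagree: "
            f"only_in_partition={sorted(part_samples - leaves)[:5]}, "
            f"only_in_tree={sorted(leaves - part_samples)[:5]}"
        )
    decisions = []
    for label in sorted(part.groups):
        members = part.groups[label]
        if len(members) == 1 and singleton_policy == "exclude":
            decisions.append(
                TreeDecision(label, 1, True, float("nan"), False, "singleton_excluded")
            )
            continue
        mono, clade = is_monophyletic(tree, members)
        if not mono:
            decisions.append(
                TreeDecision(
                    label, len(members), False, float("nan"), False, "not_monophyletic"
                )
            )
            continue
        if clade is None or clade.support is None:
            decisions.append(
                TreeDecision(
                    label, len(members), True, float("nan"), False, "no_supporting_edge"
                )
            )
            continue
        ok = clade.support > support_threshold
        decisions.append(
            TreeDecision(
                label,
                len(members),
                True,
                clade.support,
                ok,
                "monophyletic_supported" if ok else "support_too_low",
            )
        )
    return decisions


def evaluate_tree(
    matrix: AlignedMatrix,
    part: SpeciesPartition,
    model: str = "k2p",
    B: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    support_threshold: float = 0.5,
    singleton_policy: str = "exclude",
    deletion: str = "pairwise",
) -> tuple[UnrootedTree, list[TreeDecision], float]:
    """Convenience: bootstrap NJ tree, per-group decisions, and the rate."""
    tree = bootstrap_supports(matrix, model=model, B=B, seed=seed, deletion=deletion)
    decisions = tree_discriminate(
        tree, part, support_threshold=support_threshold,
        singleton_policy=singleton_policy,
    )
    return tree, decisions, discrimination_rate(decisions)
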