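"""Unrooted phylogenetic trees with branch lengths and edge supports.

The tree is stored as a rooted data structure (an arbitrary basal node, for
neighbor-joining the final three-way join point) but is interpreted as
unrooted: topology comparisons and monophyly tests go through *bipartitions*
of the leaf set, which are rooting-free.  Each edge is identified with the
child node below it; a bipartition key is the frozenset ``{side, complement}``
so that an edge and its reverse hash identically.

Newick serialisation writes branch lengths and puts edge supports on internal
node labels (the convention used by most tree viewers); parsing goes through
dendropy and is round-trip tested against the writer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import dendropy

__all__ = [
    "Clade",
    "UnrootedTree",
    "bipartition_key",
    "to_newick",
    "write_newick",
    "read_newick",
]


@dataclass
class Clade:
    """A tree node; ``length`` and ``support`` describe the edge to its parent."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_postorder(self) -> Iterator["Clade"]:
        for child in self.children:
            yield from child.iter_postorder()
        yield self


def bipartition_key(side: frozenset, universe: frozenset) -> frozenset:
    """Orientation-free key for the split ``side | universe - side``."""
    side = frozenset(side)
    return frozenset({side, frozenset(universe) - side})


class UnrootedTree:
    """Unrooted tree over uniquely-labelled leaves."""

    def __init__(self, root: Clade):
        self.root = root
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be labelled")

    # ------------------------------------------------------------------
    def leaves(self) -> list[Clade]:
        return [c for c in self.root.iter_postorder() if c.is_leaf]

    def leaf_names(self) -> list[str]:
        return [c.name for c in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def leafsets(self) -> dict[int, frozenset]:
        """Map ``id(clade) -> frozenset of leaf names below it`` (postorder)."""
        out: dict[int, frozenset] = {}
        for clade in self.root.iter_postorder():
            if clade.is_leaf:
                out[id(clade)] = frozenset({clade.name})
            else:
                out[id(clade)] = frozenset().union(
                    *(out[id(ch)] for ch in clade.children)
                )
        return out

    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset, Clade]:
        """Map bipartition key -> the clade whose parent edge induces it.

        By default only internal (informative) edges are returned, i.e. both
        sides of the split have at least two leaves.
        """
        universe = frozenset(self.leaf_names())
        leafsets = self.leafsets()
        out: dict[frozenset, Clade] = {}
        for clade in self.root.iter_postorder():
            if clade is self.root:
                continue
            below = leafsets[id(clade)]
            if not include_trivial and min(len(below), len(universe - below)) < 2:
                continue
            if len(below) == 0 or below == universe:
                continue
            out[bipartition_key(below, universe)] = clade
        return out

    def bipartition_keys(self, include_trivial: bool = False) -> set:
        return set(self.bipartitions(include_trivial=include_trivial))

    def __repr__(self) -> str:  # pragma: no cover
        return f"UnrootedTree({self.n_leaves} leaves)"


# ----------------------------------------------------------------------
# Newick

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float, clamp_negative: bool) -> str:
    if clamp_negative and x < 0:
        x = 0.0
    return format(x, ".10g")


def _clade_newick(clade: Clade, with_supports: bool, clamp: bool) -> str:
    if clade.is_leaf:
        body = _format_label(clade.name)
    else:
        inner = ",".join(
            _clade_newick(ch, with_supports, clamp) for ch in clade.children
        )
        label = ""
        if with_supports and clade.support is not None:
            label = format(clade.support, "g")
        body = f"({inner}){label}"
    return f"{body}:{_fmt_length(clade.length, clamp)}"


def to_newick(
    tree: UnrootedTree, with_supports: bool = True, clamp_negative: bool = False
) -> str:
    """Serialise to newick; edge supports become internal-node labels."""
    root = tree.root
    inner = ",".join(_clade_newick(ch, with_supports, clamp_negative) for ch in root.children)
    return f"({inner});"


def write_newick(tree: UnrootedTree, path: str | Path, **kwargs) -> None:
    if tree.n_leaves < 3:
        raise ValueError("refusing to write a tree with fewer than 3 leaves")
    Path(path).write_text(to_newick(tree, **kwargs) + "\n")


def _from_dendropy(node: dendropy.Node) -> Clade:
    if node.is_leaf():
        name = node.taxon.label if node.taxon is not None else node.label
        return Clade(name=name, length=node.edge.length or 0.0)
    support = None
    if node.label is not None:
        try:
            support = float(node.label)
        except ValueError:
            support = None
    return Clade(
        name=None,
        length=node.edge.length or 0.0,
        support=support,
        children=[_from_dendropy(ch) for ch in node.child_nodes()],
    )


def read_newick(source: str | Path) -> UnrootedTree:
    """Parse a newick tree (file path or literal string) via dendropy."""
    text = None
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        stripped = source.strip()
        if stripped.startswith("(") and stripped.endswith(";"):
            text = source
        else:
            text = Path(source).read_text()
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root = dtree.seed_node
    clade_root = Clade(
        children=[_from_dendropy(ch) for ch in root.child_nodes()]
    )
    return UnrootedTree(clade_root)
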