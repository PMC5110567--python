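"""Independent oracles used by the tests, kept free of the package's own
tree code: unrooted-topology enumeration, least-squares branch fitting, and
additive-matrix generation.

Topologies are plain edge lists over integer node ids; leaves are
``0..n-1`` (with external labels supplied separately), internal nodes are
numbered from ``n`` upward.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_topologies(n_leaves: int):
    """Yield every unrooted binary topology on ``n_leaves`` as an edge list."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    base = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]

    def _grow(edges, next_leaf, next_internal):
        if next_leaf == n_leaves:
            yield edges
            return
        for k, (u, v) in enumerate(edges):
            new = edges[:k] + edges[k + 1:]
            w = next_internal
            new += [(u, w), (w, v), (w, next_leaf)]
            yield from _grow(new, next_leaf + 1, next_internal + 1)

    yield from _grow(base, 3, n_leaves + 1)


def random_topology(n_leaves: int, rng: np.random.Generator):
    """One uniformly random-ish unrooted binary topology (random insertion)."""
    edges = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        k = int(rng.integers(len(edges)))
        u, v = edges.pop(k)
        w = next_internal
        next_internal += 1
        edges += [(u, w), (w, v), (w, leaf)]
    return edges


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def path_edge_matrix(edges, n_leaves: int) -> np.ndarray:
    """(n_pairs, n_edges) 0/1 incidence of edges on leaf-pair paths."""
    adj = _adjacency(edges)
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (a, b) in enumerate(pairs):
        # BFS path a -> b
        prev = {a: None}
        queue = [a]
        while queue:
            x = queue.pop(0)
            if x == b:
                break
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    queue.append(y)
        x = b
        while prev[x] is not None:
            A[row, edge_index[frozenset((x, prev[x]))]] = 1.0
            x = prev[x]
    return A


def additive_distances(edges, lengths, n_leaves: int) -> np.ndarray:
    """Full distance matrix implied by a topology with branch lengths."""
    A = path_edge_matrix(edges, n_leaves)
    d = A @ np.asarray(lengths)
    D = np.zeros((n_leaves, n_leaves))
    for (a, b), val in zip(itertools.combinations(range(n_leaves), 2), d):
        D[a, b] = D[b, a] = val
    return D


def topology_bipartitions(edges, labels) -> set:
    """Set of orientation-free splits (internal edges only)."""
    n = len(labels)
    universe = frozenset(labels)
    out = set()
    for e in edges:
        side = _leaves_on_side(edges, e, n)
        if min(len(side), n - len(side)) < 2:
            continue
        named = frozenset(labels[i] for i in side)
        out.add(frozenset({named, universe - named}))
    return out


def _leaves_on_side(edges, cut, n_leaves):
    u, v = cut
    adj = _adjacency([e for e in edges if frozenset(e) != frozenset(cut)])
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in adj.get(x, []):
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return [x for x in seen if x < n_leaves]


def edge_length_map(edges, lengths, labels) -> dict:
    """Orientation-free split -> branch length, including terminal edges."""
    n = len(labels)
    universe = frozenset(labels)
    out = {}
    for e, w in zip(edges, lengths):
        side = frozenset(labels[i] for i in _leaves_on_side(edges, e, n))
        out[frozenset({side, universe - side})] = w
    return out


def least_squares_best_topology(D: np.ndarray, labels):
    """Exhaustive enumeration + OLS branch fit; returns the minimum-RSS split set.

    The independent check that neighbor-joining recovered the generating
    topology of an additive matrix.
    """
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    d = D[iu]
    best = None
    for edges in enumerate_topologies(n):
        A = path_edge_matrix(edges, n)
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        rss = float(((A @ x - d) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, edges, x)
    rss, edges, x = best
    return topology_bipartitions(edges, labels), edge_length_map(edges, x, labels), rss
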