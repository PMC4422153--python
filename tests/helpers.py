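"""Independent oracles used by several test modules.

Everything here deliberately avoids the code paths it is used to check:
topology search is exhaustive least-squares over all unrooted binary trees,
alignment scoring is the plain memoized recurrence, and K2P site counting is
a dictionary-based per-column loop.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

PURINES = {"A", "G"}


# ---------------------------------------------------------------------------
# exhaustive unrooted-topology search (least-squares branch fitting)
# ---------------------------------------------------------------------------

def enumerate_topologies(leaves: list[str]):
    """All unrooted binary topologies over the leaves, as edge lists."""
    base = [("I0", leaf) for leaf in leaves[:3]]

    def rec(edges, remaining, k):
        if not remaining:
            yield edges
            return
        leaf = remaining[0]
        for i, (u, v) in enumerate(edges):
            w = f"I{k}"
            new = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (w, leaf)]
            yield from rec(new, remaining[1:], k + 1)

    yield from rec(base, leaves[3:], 1)


def _adjacency(edges):
    adj: dict[str, list[tuple[str, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    return adj


def _path_edges(adj, a, b):
    stack = [(a, None, [])]
    seen = {a}
    while stack:
        node, _, path = stack.pop()
        if node == b:
            return path
        for nxt, eidx in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append((nxt, node, path + [eidx]))
    raise RuntimeError("disconnected topology")


def topology_bipartitions(edges, leaves):
    """Canonical non-trivial bipartitions (side without the min leaf)."""
    adj = _adjacency(edges)
    ref = min(leaves)
    out = set()
    for idx, (u, v) in enumerate(edges):
        # leaves on the u side of this edge
        stack, seen = [u], {u}
        while stack:
            node = stack.pop()
            for nxt, eidx in adj[node]:
                if eidx == idx or nxt in seen:
                    continue
                seen.add(nxt)
                stack.append(nxt)
        side = frozenset(l for l in leaves if l in seen)
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(leaves) - side if ref in side else side)
    return out


def best_topology_by_least_squares(leaves, D):
    """Exhaustively fit branch lengths per topology; return the bipartition
    set of the topology with the smallest squared residual."""
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    best = None
    for edges in enumerate_topologies(list(leaves)):
        adj = _adjacency(edges)
        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for row, (i, j) in enumerate(pairs):
            for eidx in _path_edges(adj, leaves[i], leaves[j]):
                A[row, eidx] = 1.0
            y[row] = D[i, j]
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(np.sum((A @ x - y) ** 2))
        if best is None or resid < best[0]:
            best = (resid, topology_bipartitions(edges, list(leaves)))
    return best[1]


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """A random unrooted binary tree and its exact additive distance matrix."""
    leaves = [f"T{i}" for i in range(n_leaves)]
    edges = [("I0", leaf) for leaf in leaves[:3]]
    k = 1
    for leaf in leaves[3:]:
        i = int(rng.integers(0, len(edges)))
        u, v = edges.pop(i)
        w = f"I{k}"
        k += 1
        edges.extend([(u, w), (w, v), (w, leaf)])
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    adj = _adjacency(edges)
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            path = _path_edges(adj, leaves[i], leaves[j])
            D[i, j] = D[j, i] = float(sum(lengths[e] for e in path))
    return leaves, D, topology_bipartitions(edges, leaves)


# ---------------------------------------------------------------------------
# alignment scoring oracle
# ---------------------------------------------------------------------------

def brute_force_alignment_score(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Optimal global alignment score by direct recursion over all paths."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            s = (match if a[i] == b[j] else mismatch) + rec(i + 1, j + 1)
            best = s
        if i < len(a):
            s = gap + rec(i + 1, j)
            best = s if best is None else max(best, s)
        if j < len(b):
            s = gap + rec(i, j + 1)
            best = s if best is None else max(best, s)
        return best

    return rec(0, 0)


# ---------------------------------------------------------------------------
# K2P site-counting oracle
# ---------------------------------------------------------------------------

def count_sites(a: str, b: str) -> dict:
    """Comparable sites / transitions / transversions by per-column loop."""
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    return {"n": n, "transitions": ts, "transversions": tv}
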