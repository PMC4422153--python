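"""Neighbor-joining trees and column-resampling bootstrap support.

Saitou-Nei neighbor joining over a symmetric distance matrix, with a
deterministic tie-break (the lowest pair in node-creation order) and negative
branch lengths clamped to zero with a warning.  The result is an unrooted
tree represented with a trifurcating virtual root.  Bootstrap support of a
bipartition is the percentage of replicate NJ trees (built from column-
resampled alignments) that contain it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .evolution import (SaturationError, UndefinedDistanceError,
                        k2p_matrix_encoded)
from .sequtils import encode


@dataclass
class Clade:
    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())


@dataclass
class Tree:
    root: Clade          # trifurcating virtual root of the unrooted tree
    taxa: list[str]

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def _canonical(self, side: frozenset[str]) -> frozenset[str]:
        ref = min(self.taxa)
        return frozenset(self.taxa) - side if ref in side else side

    def bipartitions(self) -> dict[frozenset[str], Clade]:
        """Non-trivial bipartitions, keyed canonically (side without the
        alphabetically first taxon)."""
        out: dict[frozenset[str], Clade] = {}
        n = len(self.taxa)

        def walk(node: Clade):
            for c in node.children:
                names = c.leaf_names()
                if 1 < len(names) < n - 1:
                    out[self._canonical(names)] = c
                walk(c)
        walk(self.root)
        return out

    def has_clade(self, taxa_subset: Sequence[str]) -> bool:
        return self._canonical(frozenset(taxa_subset)) in self.bipartitions()


def validate_matrix(labels: Sequence[str], D: np.ndarray) -> None:
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match the label count")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")


def _clamp(length: float, warn: bool = True) -> float:
    if length < 0:
        if warn:
            warnings.warn("negative branch length clamped to 0", stacklevel=3)
        return 0.0
    return length


def nj_tree(labels: Sequence[str], D: np.ndarray) -> Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break toward the pair lowest in node-creation
    order (input order first, then join order).
    """
    validate_matrix(labels, D)
    D = np.asarray(D, dtype=float).copy()
    nodes: list[Clade] = [Clade(label=l) for l in labels]
    active = list(range(len(labels)))
    dist = {(i, j): D[i, j] for i in range(len(labels)) for j in range(len(labels))}
    next_id = len(labels)

    def d(i, j):
        return dist[(i, j)] if (i, j) in dist else dist[(j, i)]

    while len(active) > 3:
        r = len(active)
        R = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - R[i] - R[j]
                if best_q is None or q < best_q:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = _clamp(li), _clamp(lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = Clade(children=[child_i, child_j])
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(u, k)] = 0.5 * (d(i, k) + d(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = _clamp(0.5 * (d(a, b) + d(a, c) - d(b, c)))
    lb = _clamp(0.5 * (d(a, b) + d(b, c) - d(a, c)))
    lc = _clamp(0.5 * (d(a, c) + d(b, c) - d(a, b)))
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = ln
    root = Clade(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root, taxa=list(labels))


@dataclass
class BootstrapResult:
    tree: Tree
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_skipped: int

    def support_of(self, taxa_subset: Sequence[str]) -> float:
        key = self.tree._canonical(frozenset(taxa_subset))
        return self.supports.get(key, 0.0)

    def min_support(self, pairs: Sequence[Sequence[str]]) -> float:
        return min(self.support_of(p) for p in pairs)


def bootstrap_support(
    alignment: Mapping[str, str],
    n_replicates: int = 500,
    seed: int = 0,
) -> BootstrapResult:
    """NJ tree from K2P pairwise-deletion distances with bootstrap supports.

    Columns are resampled with replacement per replicate; replicates whose
    distance matrix is saturated or undefined are skipped and counted.
    Support is the percentage of completed replicates containing each
    bipartition of the full-data tree.  ``n_replicates=0`` returns the
    topology without supports.
    """
    labels = list(alignment)
    X = np.stack([encode(alignment[l]) for l in labels])
    if X.shape[1] < 1:
        raise ValueError("alignment has no columns")
    tree = nj_tree(labels, k2p_matrix_encoded(X))
    biparts = tree.bipartitions()
    if n_replicates == 0:
        return BootstrapResult(tree, {}, 0, 0)
    rng = np.random.default_rng(seed)
    counts = {key: 0 for key in biparts}
    done = skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate trees may clamp branches
        for _ in range(n_replicates):
            cols = rng.integers(0, X.shape[1], X.shape[1])
            try:
                D = k2p_matrix_encoded(X[:, cols])
            except (SaturationError, UndefinedDistanceError):
                skipped += 1
                continue
            rep = nj_tree(labels, D)
            rep_biparts = rep.bipartitions()
            for key in counts:
                if key in rep_biparts:
                    counts[key] += 1
            done += 1
    supports = {key: 100.0 * c / done if done else float("nan")
                for key, c in counts.items()}
    for key, node in biparts.items():
        node.support = supports[key]
    return BootstrapResult(tree, supports, n_replicates=done, n_skipped=skipped)


def sister_pairs(alignment_names: Sequence[str],
                 suffixes: tuple[str, str] = ("_5p", "_3p")) -> list[tuple[str, str]]:
    """Within-locus 5'/3' LTR pairs implied by a naming convention."""
    a, b = suffixes
    pairs = []
    for name in alignment_names:
        if name.endswith(a):
            mate = name[: -len(a)] + b
            if mate in alignment_names:
                pairs.append((name, mate))
    return pairs
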