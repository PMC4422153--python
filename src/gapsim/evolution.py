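"""Kimura two-parameter distances, inter-LTR insertion dating and site
classification.

The two LTRs of a provirus are identical at integration and diverge
independently afterwards, so their corrected pairwise distance, divided by
the per-site substitution rate, measures the time since insertion.  With a
rate mu carrying symmetric uncertainty sigma, the reported age range is
(d/(mu+sigma), d/(mu-sigma)) and the point estimate is the mean of the two
bounds.  Pairwise deletion removes, per sequence pair, only the columns that
are gapped or ambiguous in that pair.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sequtils import encode

DEFAULT_MU = 3.77e-9
DEFAULT_SIGMA = 1.33e-9


class SaturationError(ValueError):
    """The K2P logarithms are undefined: the pair is too diverged."""


class UndefinedDistanceError(ValueError):
    """No comparable sites remain after pairwise deletion."""


@dataclass(frozen=True)
class SubstitutionRate:
    """Substitutions per site per year, with symmetric uncertainty."""

    mu: float = DEFAULT_MU
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        if not self.mu > self.sigma >= 0:
            raise ValueError("require mu > sigma >= 0 (finite age bounds)")


@dataclass(frozen=True)
class K2PResult:
    P: float        # transition proportion
    Q: float        # transversion proportion
    n_sites: int    # compared sites after pairwise deletion
    d: float        # corrected distance

    @property
    def p_distance(self) -> float:
        return self.P + self.Q


def k2p_from_counts(n_sites: int, transitions: int, transversions: int) -> K2PResult:
    """K2P distance from site counts: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    if n_sites <= 0:
        raise UndefinedDistanceError("no comparable sites")
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated pair: P={P:.4g}, Q={Q:.4g}")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K2PResult(P=P, Q=Q, n_sites=n_sites, d=float(d))


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    diff = valid & (a != b)
    purine_a = (a == 0) | (a == 2)
    purine_b = (b == 0) | (b == 2)
    ts = int((diff & (purine_a == purine_b)).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def pairwise_k2p(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance of two aligned sequences under pairwise deletion.

    Columns where either sequence holds a gap or any non-ACGT code are
    excluded.  Raises :class:`SaturationError` when the correction is
    undefined and :class:`UndefinedDistanceError` when nothing is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n, ts, tv = _pair_counts(encode(seq_a), encode(seq_b))
    return k2p_from_counts(n, ts, tv)


def k2p_matrix(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """Symmetric K2P distance matrix over an aligned sequence dict."""
    labels = list(alignment)
    X = np.stack([encode(alignment[l]) for l in labels])
    return labels, k2p_matrix_encoded(X)


def k2p_matrix_encoded(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    valid = X >= 0
    purine = (X == 0) | (X == 2)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = valid[i] & valid[j]
            nv = int(v.sum())
            if nv == 0:
                raise UndefinedDistanceError(f"no comparable sites for pair {i},{j}")
            diff = v & (X[i] != X[j])
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            D[i, j] = D[j, i] = k2p_from_counts(nv, ts, tv).d
    return D


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeEstimate:
    """Inter-LTR divergence and insertion-age estimate in years."""

    d: float
    t_low: float
    t_high: float
    t_mean: float

    def in_mya(self) -> tuple[float, float, float]:
        return (self.t_low / 1e6, self.t_high / 1e6, self.t_mean / 1e6)

    def __str__(self) -> str:
        lo, hi, mean = self.in_mya()
        return f"{mean:.2f} Mya ({lo:.2f}-{hi:.2f})"


def estimate_age(d: float, rate: SubstitutionRate = SubstitutionRate()) -> AgeEstimate:
    """Insertion age from inter-LTR divergence.

    t_low = d/(mu+sigma), t_high = d/(mu-sigma), point estimate the mean of
    the bounds.  d = 0 gives a zero age.
    """
    if d < 0:
        raise ValueError("divergence must be >= 0")
    t_low = d / (rate.mu + rate.sigma)
    t_high = d / (rate.mu - rate.sigma)
    return AgeEstimate(d=d, t_low=t_low, t_high=t_high,
                       t_mean=0.5 * (t_low + t_high))


# ---------------------------------------------------------------------------
# variable-site classification
# ---------------------------------------------------------------------------

@dataclass
class SiteClassification:
    labels: list[str]               # per column: invariant|singleton|parsimony_informative

    @property
    def counts(self) -> dict[str, int]:
        out = {"invariant": 0, "singleton": 0, "parsimony_informative": 0}
        for l in self.labels:
            out[l] += 1
        return out

    @property
    def n_variable(self) -> int:
        c = self.counts
        return c["singleton"] + c["parsimony_informative"]

    def positions(self, label: str) -> list[int]:
        """1-based alignment positions carrying the given label."""
        return [i + 1 for i, l in enumerate(self.labels) if l == label]


def variable_sites(alignment: Mapping[str, str]) -> SiteClassification:
    """Classify alignment columns as invariant, singleton or parsimony
    informative.  A column is parsimony informative when at least two states
    are each carried by at least two sequences; gaps and ambiguities are
    treated as missing.
    """
    seqs = list(alignment.values())
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    X = np.stack([encode(s) for s in seqs])
    labels = []
    for col in X.T:
        states, counts = np.unique(col[col >= 0], return_counts=True)
        if len(states) <= 1:
            labels.append("invariant")
        elif (counts >= 2).sum() >= 2:
            labels.append("parsimony_informative")
        else:
            labels.append("singleton")
    return SiteClassification(labels=labels)


# ---------------------------------------------------------------------------
# pairwise global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: int


def align_pair(seq_a: str, seq_b: str, match: int = 1, mismatch: int = -1,
               gap: int = -2) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with linear gap cost.

    Traceback is deterministic, preferring diagonal over a gap in the second
    sequence over a gap in the first.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    F = np.zeros((n + 1, m + 1), dtype=np.int64)
    F[:, 0] = gap * np.arange(n + 1)
    F[0, :] = gap * np.arange(m + 1)
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    sub = np.where(a[:, None] == b[None, :], match, mismatch)
    for i in range(1, n + 1):
        row_prev = F[i - 1]
        row = F[i]
        for j in range(1, m + 1):
            row[j] = max(row_prev[j - 1] + sub[i - 1, j - 1],
                         row_prev[j] + gap,
                         row[j - 1] + gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(seq_a[i - 1]); out_b.append(seq_b[j - 1])
            i -= 1; j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            out_a.append(seq_a[i - 1]); out_b.append("-")
            i -= 1
        else:
            out_a.append("-"); out_b.append(seq_b[j - 1])
            j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                             int(F[n, m]))
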