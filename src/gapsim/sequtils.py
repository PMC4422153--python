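"""Low-level nucleotide helpers shared across the package.

Sequences are plain upper-case Python strings over the IUPAC DNA alphabet.
Numeric work uses an int8 encoding (A=0, C=1, G=2, T=3, anything else -1);
encoded arrays are the interchange format for the distance and bootstrap
machinery.
"""
from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

_FWD = "ACGTRYSWKMBDHVN"
_REV = "TGCAYRSWMKVHDBN"
_COMPLEMENT = str.maketrans(_FWD + _FWD.lower(), _REV + _REV.lower())

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
IUPAC_LETTERS = frozenset(_FWD)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware, case-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes; gaps/ambiguities become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    if np.any(codes < 0):
        raise ValueError("cannot decode codes containing -1")
    return _DECODE[codes].tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    """I.i.d. random sequence at the given GC content."""
    p = np.array([(1.0 - gc) / 2, gc / 2, gc / 2, (1.0 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _DECODE[idx].tobytes().decode("ascii")


def _windows_to_mask(length: int, windows: Iterable[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in windows:
        mask[max(start, 0):min(end, length)] = True
    return mask


def mutate(
    rng: np.random.Generator,
    seq: str,
    p_sub: float | None = None,
    n_sub: int | None = None,
    ts_tv_ratio: float = 2.0,
    protect: Iterable[tuple[int, int]] | None = None,
) -> str:
    """Apply independent per-site substitutions to ``seq``.

    Exactly one of ``p_sub`` (per-site substitution probability) or ``n_sub``
    (exact substitution count at distinct positions) must be given.
    Transitions are favoured over transversions by ``ts_tv_ratio`` (may be
    ``inf`` for transitions only).  ``protect`` lists half-open windows that
    must not mutate.  Sites that are not A/C/G/T are left untouched.
    """
    if (p_sub is None) == (n_sub is None):
        raise ValueError("give exactly one of p_sub or n_sub")
    codes = encode(seq)
    eligible = codes >= 0
    if protect is not None:
        eligible &= ~_windows_to_mask(len(seq), protect)
    candidates = np.flatnonzero(eligible)
    if p_sub is not None:
        if p_sub < 0:
            raise ValueError("p_sub must be >= 0")
        hit = candidates[rng.random(candidates.size) < p_sub]
    else:
        if n_sub < 0:
            raise ValueError("n_sub must be >= 0")
        if n_sub > candidates.size:
            raise ValueError("n_sub exceeds mutable sites")
        hit = rng.choice(candidates, size=n_sub, replace=False)
    if hit.size == 0:
        return seq
    out = list(seq)
    p_ts = 1.0 if np.isinf(ts_tv_ratio) else ts_tv_ratio / (ts_tv_ratio + 1.0)
    draws = rng.random(hit.size)
    picks = rng.integers(0, 2, size=hit.size)
    for k, pos in enumerate(hit):
        base = out[pos]
        if draws[k] < p_ts:
            out[pos] = TRANSITION[base]
        else:
            # the two transversion partners of each base
            tv = [b for b in BASES if b != base and b != TRANSITION[base]]
            out[pos] = tv[picks[k]]
    return "".join(out)


def iupac_regex(recognition: str) -> re.Pattern:
    """Compile an overlap-tolerant regex for an IUPAC recognition string."""
    classes = []
    for ch in recognition.upper():
        try:
            classes.append("[%s]" % ambiguous_dna_values[ch])
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
    return re.compile("(?=(" + "".join(classes) + "))")


def find_iupac(seq: str, recognition: str) -> list[int]:
    """Start positions of (possibly overlapping) IUPAC pattern matches."""
    pat = iupac_regex(recognition)
    return [m.start() for m in pat.finditer(seq.upper())]


def find_all(seq: str, sub: str) -> list[int]:
    """All (overlapping) exact occurrences of ``sub`` in ``seq``."""
    out = []
    i = seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)
    return out
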