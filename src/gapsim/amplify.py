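"""Suppression PCR and nested enrichment over linkered restriction fragments.

The first round pairs a proviral target primer (gag for the 5' assay, env for
the 3' assay) with a linker primer.  Fragments linkered at both ends form
stem-loops that suppress amplification, so a fragment yields a product only
when the target primer anneals inside it; the product runs from the target
primer to the fragment's linkered end.  A second, nested round with an
LTR primer oriented toward the linker end enriches for LTR-flank junction
fragments and shortens products, after which a gel-window size filter is
applied.  Solo LTRs and SVA-like decoys carry no gag/env site and therefore
never amplify — the selectivity the protocol is built on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .restriction import VSPI, Fragment, RestrictionEnzyme, digest, ligate_linkers
from .sequtils import encode, revcomp
from .simulate import ProviralTemplate

PRIMER_ROLES = ("target", "nested_ltr", "linker", "nested_linker", "flank")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    role: str = "target"
    max_mismatches: int = 0
    three_prime_exact: int = 3
    allow_short: bool = False

    def __post_init__(self):
        if self.role not in PRIMER_ROLES:
            raise ValueError(f"unknown primer role {self.role!r}")
        if len(self.sequence) < 15 and not self.allow_short:
            raise ValueError("primer shorter than 15 nt; pass allow_short=True")
        if self.max_mismatches < 0 or self.three_prime_exact < 0:
            raise ValueError("mismatch parameters must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSite:
    """A primer binding window: ``start`` is the leftmost base of the match."""

    start: int
    strand: str
    mismatches: int

    def five_prime_pos(self, primer_len: int) -> int:
        return self.start if self.strand == "+" else self.start + primer_len - 1


def _scan(seq_codes: np.ndarray, primer_codes: np.ndarray,
          max_mm: int, tp_exact: int, tp_at_end: bool) -> list[tuple[int, int]]:
    """(start, mismatches) of windows matching the primer on one strand."""
    L = primer_codes.size
    if seq_codes.size < L:
        return []
    win = np.lib.stride_tricks.sliding_window_view(seq_codes, L)
    mm = win != primer_codes
    total = mm.sum(axis=1)
    ok = total <= max_mm
    if tp_exact > 0:
        exact = mm[:, -tp_exact:] if tp_at_end else mm[:, :tp_exact]
        ok &= ~exact.any(axis=1)
    starts = np.flatnonzero(ok)
    return [(int(s), int(total[s])) for s in starts]


def find_primer_sites(sequence: str, primer: Primer) -> list[PrimerSite]:
    """All binding sites of ``primer`` on both strands of ``sequence``.

    Hits honour ``max_mismatches`` overall and require the 3'-terminal
    ``three_prime_exact`` bases to match exactly; results are sorted by
    position.  On the '+' strand the primer's 3' end is the right edge of the
    window; on the '-' strand it is the left edge.
    """
    codes = encode(sequence.upper())
    fwd = encode(primer.sequence.upper())
    rev = encode(revcomp(primer.sequence.upper()))
    sites = [
        PrimerSite(s, "+", mm)
        for s, mm in _scan(codes, fwd, primer.max_mismatches,
                           primer.three_prime_exact, tp_at_end=True)
    ] + [
        PrimerSite(s, "-", mm)
        for s, mm in _scan(codes, rev, primer.max_mismatches,
                           primer.three_prime_exact, tp_at_end=False)
    ]
    return sorted(sites, key=lambda s: (s.start, s.strand))


@dataclass
class Product:
    """A first-round suppression-PCR product within one fragment."""

    fragment: Fragment
    start: int            # local, within the fragment
    end: int
    linker_end: str       # 'left' | 'right' — the end carrying the linker
    length: int           # includes the full linker at the linkered terminus

    @property
    def sequence(self) -> str:
        return self.fragment.sequence[self.start:self.end]


@dataclass
class Amplicon:
    """A nested-PCR product with genomic coordinates on the source contig."""

    contig: str
    start: int
    end: int
    mode: str             # 'five_prime' | 'three_prime'
    ltr_end: str          # which genomic end of the span abuts the LTR primer
    length: int           # genomic span + nested linker primer contribution
    sequence: str         # plus-strand genomic substring
    fragment_id: str = ""

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.mode}"


def suppression_pcr(
    fragments: Sequence[Fragment],
    target_primer: Primer,
    min_product: int = 50,
    max_first_round: int = 5000,
) -> list[Product]:
    """First-round products: one per target-primer site per linkered fragment."""
    products: list[Product] = []
    seen: set[tuple[str, int, int]] = set()
    for frag in fragments:
        for site in find_primer_sites(frag.sequence, target_primer):
            if site.strand == "+":
                if not frag.linkered_right:
                    continue
                start, end, linker_end = site.start, frag.length, "right"
            else:
                if not frag.linkered_left:
                    continue
                start, end, linker_end = 0, site.start + len(target_primer), "left"
            length = (end - start) + frag.linker_length
            if not min_product <= length <= max_first_round:
                continue
            key = (frag.id, start, end)
            if key in seen:
                continue
            seen.add(key)
            products.append(Product(frag, start, end, linker_end, length))
    return products


def nested_pcr(
    products: Sequence[Product],
    ltr_primer: Primer,
    nested_linker_length: int = 25,
    size_window: tuple[int, int] = (100, 3000),
    mode: str = "five_prime",
) -> list[Amplicon]:
    """Retain products in which the LTR primer points at the linker end.

    The amplicon runs from the LTR primer's 5' end to the linker end; the
    nested linker primer adds ``nested_linker_length`` to the product length.
    Amplicons are deduplicated by genomic span.
    """
    lo, hi = size_window
    amplicons: dict[tuple[str, int, int], Amplicon] = {}
    for prod in products:
        sub = prod.sequence
        for site in find_primer_sites(sub, ltr_primer):
            if site.strand == "+" and prod.linker_end == "right":
                a0 = prod.start + site.start
                a1 = prod.end
                ltr_end = "left"
            elif site.strand == "-" and prod.linker_end == "left":
                a0 = prod.start
                a1 = prod.start + site.start + len(ltr_primer)
                ltr_end = "right"
            else:
                continue
            length = (a1 - a0) + nested_linker_length
            if not lo <= length <= hi:
                continue
            frag = prod.fragment
            g0, g1 = frag.start + a0, frag.start + a1
            key = (frag.contig, g0, g1)
            if key not in amplicons:
                amplicons[key] = Amplicon(
                    contig=frag.contig, start=g0, end=g1, mode=mode,
                    ltr_end=ltr_end, length=length,
                    sequence=frag.sequence[a0:a1], fragment_id=frag.id,
                )
    return sorted(amplicons.values(), key=lambda a: (a.contig, a.start, a.end))


@dataclass
class GapsConfig:
    """Everything one assay run needs: enzyme, primers, sizes, windows."""

    enzyme: RestrictionEnzyme = VSPI
    target_5p: Primer | None = None
    target_3p: Primer | None = None
    nested_5p: Primer | None = None
    nested_3p: Primer | None = None
    nested_5p_ltr_offset: int = 0   # leftmost base of the window in the LTR
    nested_3p_ltr_offset: int = 0
    ltr_length: int = 968
    linker_length: int = 40
    nested_linker_length: int = 25
    size_window: tuple[int, int] = (100, 3000)
    min_product: int = 50
    max_first_round: int = 5000

    def primers_for(self, mode: str) -> tuple[Primer, Primer]:
        mode = normalize_mode(mode)
        target = self.target_5p if mode == "five_prime" else self.target_3p
        nested = self.nested_5p if mode == "five_prime" else self.nested_3p
        missing = [
            name for name, p in
            (("target", target), ("nested_ltr", nested)) if p is None
        ]
        if missing:
            raise ValueError(
                f"config lacks {' and '.join(missing)} primer(s) for mode {mode}"
            )
        return target, nested

    def ltr_part_length(self, mode: str) -> int:
        """Bases of LTR contained in an amplicon of the given mode."""
        mode = normalize_mode(mode)
        if mode == "five_prime":
            return self.nested_5p_ltr_offset + len(self.nested_5p)
        return self.ltr_length - self.nested_3p_ltr_offset

    @classmethod
    def from_template(cls, template: ProviralTemplate, **overrides) -> "GapsConfig":
        """Derive the full primer set from a template's anchor windows."""
        mk = lambda name, role: Primer(
            name=name, sequence=template.primer_seq(name), role=role)
        cfg = cls(
            target_5p=mk("GAG", "target"),
            target_3p=mk("ENV", "target"),
            nested_5p=mk("LTR5", "nested_ltr"),
            nested_3p=mk("LTR3", "nested_ltr"),
            nested_5p_ltr_offset=template.anchors["LTR5"].offset,
            nested_3p_ltr_offset=template.anchors["LTR3"].offset,
            ltr_length=len(template.ltr),
        )
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise TypeError(f"unknown config field {key!r}")
            setattr(cfg, key, val)
        return cfg


def normalize_mode(mode: str) -> str:
    aliases = {"5p": "five_prime", "five_prime": "five_prime",
               "3p": "three_prime", "three_prime": "three_prime"}
    try:
        return aliases[mode]
    except KeyError:
        raise ValueError(f"mode must be 5p or 3p, got {mode!r}")


LOG_COLUMNS = ["fragment", "length", "n_target_sites", "n_products",
               "n_amplicons", "outcome"]


def run_gaps(
    genome: Mapping[str, str],
    config: GapsConfig,
    mode: str,
) -> tuple[list[Amplicon], pd.DataFrame]:
    """Digest -> ligate -> suppression -> nested -> size filter, with a log.

    The log records one row per fragment and why it dropped out: no target
    site (suppression), product outside the first-round size limits, no
    correctly oriented LTR site (e.g. internal truncation by a cut site), or
    amplicon outside the gel window.
    """
    mode = normalize_mode(mode)
    target, nested = config.primers_for(mode)
    fragments = ligate_linkers(
        digest(genome, config.enzyme), linker_length=config.linker_length)
    amplicons: list[Amplicon] = []
    log_rows = []
    for frag in fragments:
        sites = find_primer_sites(frag.sequence, target)
        prods = suppression_pcr(
            [frag], target,
            min_product=config.min_product,
            max_first_round=config.max_first_round)
        amps = nested_pcr(
            prods, nested,
            nested_linker_length=config.nested_linker_length,
            size_window=config.size_window, mode=mode)
        if not sites:
            outcome = "suppressed_no_target_site"
        elif not prods:
            outcome = "first_round_size_fail_or_no_linker"
        elif not amps:
            raw = nested_pcr(prods, nested,
                             nested_linker_length=config.nested_linker_length,
                             size_window=(0, 10**9), mode=mode)
            outcome = ("amplicon_outside_size_window" if raw
                       else "no_oriented_ltr_site")
        else:
            outcome = "amplified"
        log_rows.append({
            "fragment": frag.id, "length": frag.length,
            "n_target_sites": len(sites), "n_products": len(prods),
            "n_amplicons": len(amps), "outcome": outcome,
        })
        amplicons.extend(amps)
    # dedupe across fragments by genomic span
    uniq: dict[tuple[str, int, int], Amplicon] = {}
    for a in amplicons:
        uniq.setdefault((a.contig, a.start, a.end), a)
    out = sorted(uniq.values(), key=lambda a: (a.contig, a.start, a.end))
    return out, pd.DataFrame(log_rows, columns=LOG_COLUMNS)
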