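"""Synthetic genomes, proviral elements and diploid populations with known truth.

The generator emulates the genomic substrate the suppression-PCR protocol is
designed for: full-length HERV-K(HML-2)-style proviruses (5'LTR - gag - pro -
pol - env - 3'LTR, ~9.5 kb with ~968 bp LTRs), the Type I variant carrying a
292 bp deletion at the pol-env boundary, 4-6 bp target-site duplications plus
long degenerate ones, solo LTRs left by inter-LTR recombination, SVA-like
decoys (LTR-derived sequence without gag/env), independent post-insertion LTR
divergence, and diploid populations drawn under Hardy-Weinberg from planted
allele frequencies.  Every generated genome is accompanied by a machine-
readable truth table so downstream stages can be scored exactly.

Coordinates are 0-based half-open throughout.  Truth spans run between the
outer edges of the two TSD copies.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .restriction import VSPI, RestrictionEnzyme
from .sequtils import find_all, mutate, random_seq, revcomp

DIAG_LEN = 292          # length of the pol-env boundary segment absent from Type I
DEFAULT_LTR_LEN = 968
DEFAULT_RATE = 3.77e-9  # substitutions / site / year
MAX_TSD = 30

STATES = ("provirus", "solo_ltr", "pre_insertion")


class OverlappingInsertionsError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerAnchor:
    """Location of a primer binding window inside a template region.

    ``offset`` is the leftmost base of the window within the region; primers
    on the '-' strand anneal to the top-strand window and extend leftward.
    """

    region: str
    offset: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class ProviralTemplate:
    """Sequence template of a full-length provirus and its primer anchors."""

    ltr: str
    gag: str
    pro: str
    pol: str
    env: str
    anchors: Mapping[str, PrimerAnchor]
    primer_length: int = 20
    diag_len: int = DIAG_LEN

    def __post_init__(self):
        if self.diag_len % 2:
            raise ValueError("diag_len must be even")
        half = self.diag_len // 2
        if len(self.pol) < half or len(self.env) < half:
            raise ValueError("pol/env too short to span the diagnostic segment")
        for name in ("GAG", "ENV", "LTR5", "LTR3"):
            if name not in self.anchors:
                raise ValueError(f"template missing anchor {name}")

    # --- sequence views ---------------------------------------------------
    @property
    def diagnostic(self) -> str:
        """The diag_len segment spanning the pol-env boundary (Type II only)."""
        half = self.diag_len // 2
        return self.pol[-half:] + self.env[:half]

    @property
    def internal_type2(self) -> str:
        return self.gag + self.pro + self.pol + self.env

    @property
    def internal_type1(self) -> str:
        half = self.diag_len // 2
        return self.gag + self.pro + self.pol[:-half] + self.env[half:]

    def internal(self, subtype: str) -> str:
        if subtype == "II":
            return self.internal_type2
        if subtype == "I":
            return self.internal_type1
        raise ValueError(f"unknown subtype {subtype!r}")

    @property
    def diag_start_internal(self) -> int:
        """Start of the diagnostic segment within the Type II internal sequence."""
        return len(self.gag) + len(self.pro) + len(self.pol) - self.diag_len // 2

    def provirus_core(self, subtype: str = "II") -> str:
        return self.ltr + self.internal(subtype) + self.ltr

    def region_seq(self, name: str) -> str:
        return getattr(self, name)

    def primer_window(self, name: str) -> str:
        a = self.anchors[name]
        region = self.region_seq(a.region)
        return region[a.offset:a.offset + self.primer_length]

    def primer_seq(self, name: str) -> str:
        """Primer sequence 5'->3' as it would be synthesised."""
        window = self.primer_window(name)
        a = self.anchors[name]
        return window if a.strand == "+" else revcomp(window)

    def validate(self) -> None:
        if self.diagnostic not in self.internal_type2:
            raise AssertionError("diagnostic segment absent from Type II internal")
        if find_all(self.internal_type2, self.diagnostic) != [self.diag_start_internal]:
            raise AssertionError("diagnostic segment not unique in Type II internal")
        if self.diagnostic in self.internal_type1:
            raise AssertionError("diagnostic segment present in Type I internal")
        assert len(self.internal_type2) - len(self.internal_type1) == self.diag_len


def _scrub_pattern(rng, seq_list: list[str], pattern: str) -> None:
    """Destroy all occurrences of pattern (both strands) by point changes."""
    for pat in {pattern, revcomp(pattern)}:
        s = "".join(seq_list)
        for pos in find_all(s, pat):
            mid = pos + len(pat) // 2
            old = seq_list[mid]
            choices = [b for b in "ACGT" if b != old]
            seq_list[mid] = choices[rng.integers(0, 3)]
    s = "".join(seq_list)
    if pattern in s or revcomp(pattern) in s:
        _scrub_pattern(rng, seq_list, pattern)


def default_template(
    seed: int = 0,
    ltr_len: int = DEFAULT_LTR_LEN,
    gag_len: int = 2100,
    pro_len: int = 750,
    pol_len: int = 2600,
    env_len: int = 2086,
    gc: float = 0.41,
    enzyme: RestrictionEnzyme = VSPI,
    primer_length: int = 20,
) -> ProviralTemplate:
    """A reproducible random template free of internal restriction sites.

    Default region lengths give a 9,472 bp Type II provirus with 968 bp LTRs.
    The enzyme recognition site is scrubbed from all regions so that, unless a
    fixture plants one deliberately, restriction geometry is controlled by the
    background alone.
    """
    rng = np.random.default_rng(seed)
    regions = {}
    for name, length in (
        ("ltr", ltr_len), ("gag", gag_len), ("pro", pro_len),
        ("pol", pol_len), ("env", env_len),
    ):
        chars = list(random_seq(rng, length, gc))
        _scrub_pattern(rng, chars, enzyme.recognition)
        regions[name] = "".join(chars)
    anchors = {
        "GAG": PrimerAnchor("gag", 300, "-"),
        "ENV": PrimerAnchor("env", env_len - 320, "+"),
        "LTR5": PrimerAnchor("ltr", 40, "-"),
        "LTR3": PrimerAnchor("ltr", ltr_len - 60, "+"),
    }
    tpl = ProviralTemplate(anchors=anchors, primer_length=primer_length, **regions)
    tpl.validate()
    return tpl


# ---------------------------------------------------------------------------
# elements
# ---------------------------------------------------------------------------

@dataclass
class Element:
    """A planted element in local (plus-strand) coordinates, TSDs included."""

    seq: str
    kind: str                   # 'provirus' | 'solo_ltr'
    subtype: str | None         # 'I' | 'II' | None
    tsd: str
    tsd2: str                   # downstream copy (may carry planted mismatches)
    ltr5: tuple[int, int]
    ltr3: tuple[int, int] | None
    anchors: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.seq)


def make_provirus(
    template: ProviralTemplate,
    subtype: str = "II",
    tsd: str = "",
    orientation: str = "+",
    tsd_mismatches: int = 0,
    allow_long_tsd: bool = False,
    rng: np.random.Generator | None = None,
) -> Element:
    """Assemble a full provirus flanked by its two TSD copies.

    The element is always built in plus orientation; ``orientation`` is applied
    by the genome builder at insertion time.  ``tsd_mismatches`` plants
    substitutions into the downstream TSD copy to emulate long degenerate
    direct repeats.
    """
    if orientation not in "+-":
        raise ValueError("orientation must be '+' or '-'")
    if len(tsd) > MAX_TSD and not allow_long_tsd:
        raise ValueError(
            f"TSD of {len(tsd)} bp exceeds {MAX_TSD}; pass allow_long_tsd=True"
        )
    tsd2 = tsd
    if tsd_mismatches:
        rng = rng if rng is not None else np.random.default_rng(0)
        tsd2 = mutate(rng, tsd, n_sub=tsd_mismatches)
    internal = template.internal(subtype)
    L = len(template.ltr)
    t = len(tsd)
    core = template.ltr + internal + template.ltr
    seq = tsd + core + tsd2
    ltr5 = (t, t + L)
    ltr3 = (t + L + len(internal), t + L + len(internal) + L)
    plen = template.primer_length
    # region offsets within the internal sequence
    gag_start = t + L
    env_off = template.anchors["ENV"].offset
    if subtype == "II":
        env_start_internal = len(template.gag) + len(template.pro) + len(template.pol)
        env_anchor_internal = env_start_internal + env_off
    else:
        half = template.diag_len // 2
        env_anchor_internal = (
            len(template.gag) + len(template.pro) + len(template.pol) - half
            + (env_off - half)
        )
    anchors = {
        "GAG": (gag_start + template.anchors["GAG"].offset,
                gag_start + template.anchors["GAG"].offset + plen, "-"),
        "ENV": (t + L + env_anchor_internal, t + L + env_anchor_internal + plen, "+"),
        "LTR5": (ltr5[0] + template.anchors["LTR5"].offset,
                 ltr5[0] + template.anchors["LTR5"].offset + plen, "-"),
        "LTR3": (ltr3[0] + template.anchors["LTR3"].offset,
                 ltr3[0] + template.anchors["LTR3"].offset + plen, "+"),
    }
    el = Element(seq=seq, kind="provirus", subtype=subtype, tsd=tsd, tsd2=tsd2,
                 ltr5=ltr5, ltr3=ltr3, anchors=anchors)
    for name, (a0, a1, strand) in anchors.items():
        assert el.seq[a0:a1] == template.primer_window(name), name
    return el


def evolve_ltr_pair(
    element: Element,
    time_years: float,
    rate_per_site_year: float = DEFAULT_RATE,
    ts_tv_ratio: float = 2.0,
    seed: int = 0,
    protect_primer_sites: bool = False,
) -> Element:
    """Mutate the 5' and 3' LTRs independently for ``time_years`` years.

    Substitutions are drawn per site with probability rate x time, so the
    expected pairwise difference count between the two LTRs is
    2 x LTR-length x rate x time.  With ``protect_primer_sites`` the nested
    LTR primer windows are excluded from mutation (the assay's view of a
    locus then stays a pure function of restriction geometry).
    """
    if rate_per_site_year < 0 or time_years < 0:
        raise ValueError("rate and time must be >= 0")
    if element.ltr3 is None:
        raise ValueError("element does not carry two LTRs")
    rng = np.random.default_rng(seed)
    p = rate_per_site_year * time_years
    seq = element.seq
    pieces = []
    prev = 0
    for span in (element.ltr5, element.ltr3):
        s0, s1 = span
        protect = None
        if protect_primer_sites:
            protect = [
                (a0 - s0, a1 - s0)
                for (a0, a1, _) in element.anchors.values()
                if s0 <= a0 and a1 <= s1
            ]
        mutated = mutate(rng, seq[s0:s1], p_sub=p, ts_tv_ratio=ts_tv_ratio,
                         protect=protect)
        pieces.append(seq[prev:s0])
        pieces.append(mutated)
        prev = s1
    pieces.append(seq[prev:])
    out = Element(**{**element.__dict__, "seq": "".join(pieces)})
    return out


def make_solo_ltr(element: Element, breakpoint: int | None = None) -> Element:
    """Collapse a provirus to a solo LTR by inter-LTR recombination.

    The retained LTR is a 5'/3' recombinant: positions at or beyond
    ``breakpoint`` come from the 5' LTR, the rest from the 3' LTR (default
    midpoint), so breakpoint 0 retains the 5' LTR verbatim and breakpoint
    at the LTR end retains the 3' LTR.  The original TSD copies remain.
    """
    if element.ltr3 is None:
        raise ValueError("input element lacks two LTRs")
    ltr5_seq = element.seq[element.ltr5[0]:element.ltr5[1]]
    ltr3_seq = element.seq[element.ltr3[0]:element.ltr3[1]]
    if len(ltr5_seq) != len(ltr3_seq):
        raise ValueError("LTRs of unequal length cannot recombine positionally")
    bp = len(ltr5_seq) // 2 if breakpoint is None else breakpoint
    if not 0 <= bp <= len(ltr5_seq):
        raise ValueError("breakpoint outside the LTR")
    recomb = ltr3_seq[:bp] + ltr5_seq[bp:]
    t = len(element.tsd)
    seq = element.tsd + recomb + element.tsd2
    return Element(
        seq=seq, kind="solo_ltr", subtype=None, tsd=element.tsd,
        tsd2=element.tsd2, ltr5=(t, t + len(recomb)), ltr3=None, anchors={},
    )


def make_sva_decoy(
    template: ProviralTemplate,
    rng: np.random.Generator,
    length: int = 1500,
    gc: float = 0.55,
) -> str:
    """An SVA-like decoy: LTR-derived sequence plus a GC-rich VNTR-like tract.

    Decoys carry no gag/env target-primer sites, so a selective assay must
    produce nothing from them.
    """
    ltr_part = template.ltr[100:100 + min(700, length // 2)]
    vntr = random_seq(rng, max(length - len(ltr_part), 0), gc)
    seq = list(ltr_part + vntr)
    for name in ("GAG", "ENV"):
        _scrub_pattern(rng, seq, template.primer_window(name))
    return "".join(seq)


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionSpec:
    """Recipe for one planted locus."""

    locus_id: str
    position: int                      # insertion point in background coordinates
    allelic_state: str = "provirus"    # provirus | solo_ltr | pre_insertion
    subtype: str = "II"
    tsd: str = ""
    tsd_mismatches: int = 0
    ltr_divergence_time: float = 0.0   # years of independent LTR evolution
    orientation: str = "+"
    solo_breakpoint: int | None = None
    allow_long_tsd: bool = False

    def __post_init__(self):
        if self.allelic_state not in STATES:
            raise ValueError(f"unknown allelic state {self.allelic_state!r}")


@dataclass
class PlantedElement:
    """Genome-level truth annotation of one planted locus."""

    locus_id: str
    contig: str
    start: int                 # outer edge of the upstream TSD copy
    end: int                   # outer edge of the downstream TSD copy
    state: str
    subtype: str | None
    tsd: str
    tsd2: str
    orientation: str
    ltr5_span: tuple[int, int] | None = None
    ltr3_span: tuple[int, int] | None = None
    anchors: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    @property
    def junction5(self) -> int:
        """Genomic LTR-flank junction on the element's left side."""
        return self.start + len(self.tsd)

    @property
    def junction3(self) -> int:
        return self.end - len(self.tsd2)


@dataclass
class SimGenome:
    contig: str
    seq: str
    truth: pd.DataFrame
    elements: dict[str, PlantedElement]
    decoys: pd.DataFrame
    template: ProviralTemplate
    background: str
    enzyme: RestrictionEnzyme

    def as_dict(self) -> dict[str, str]:
        return {self.contig: self.seq}


def _element_for(spec: InsertionSpec, template: ProviralTemplate,
                 rng: np.random.Generator) -> Element | None:
    if spec.allelic_state == "pre_insertion":
        return None
    el = make_provirus(
        template, subtype=spec.subtype, tsd=spec.tsd,
        tsd_mismatches=spec.tsd_mismatches,
        allow_long_tsd=spec.allow_long_tsd, rng=rng,
    )
    if spec.ltr_divergence_time > 0:
        el = evolve_ltr_pair(
            el, spec.ltr_divergence_time,
            seed=int(rng.integers(0, 2**31)),
            protect_primer_sites=True,
        )
    if spec.allelic_state == "solo_ltr":
        el = make_solo_ltr(el, breakpoint=spec.solo_breakpoint)
    return el


def _orient(el: Element, orientation: str) -> Element:
    if orientation == "+":
        return el
    n = len(el.seq)
    flip = lambda span: (n - span[1], n - span[0])
    anchors = {
        name: (n - a1, n - a0, "+" if s == "-" else "-")
        for name, (a0, a1, s) in el.anchors.items()
    }
    ltr5 = flip(el.ltr5)
    ltr3 = flip(el.ltr3) if el.ltr3 is not None else None
    return Element(seq=revcomp(el.seq), kind=el.kind, subtype=el.subtype,
                   tsd=revcomp(el.tsd2), tsd2=revcomp(el.tsd),
                   ltr5=ltr5, ltr3=ltr3, anchors=anchors)


TRUTH_COLUMNS = ["locus_id", "contig", "start", "end", "state", "subtype", "tsd"]


def build_genome(
    template: ProviralTemplate,
    background_length: int,
    insertions: Sequence[InsertionSpec],
    decoys: int = 0,
    gc: float = 0.41,
    seed: int = 0,
    enzyme: RestrictionEnzyme = VSPI,
    site_plan: Mapping[str, Mapping[str, int]] | None = None,
    clear_natural_sites: bool = False,
    contig: str = "chr1",
    background: str | None = None,
) -> SimGenome:
    """Assemble a single-contig genome with planted elements and truth.

    ``site_plan`` maps locus_id -> {'five': d5, 'three': d3}: a restriction
    site is written into the background so that the nearest cut lands exactly
    ``d`` bp from the corresponding element edge.  ``clear_natural_sites``
    first removes every chance occurrence of the recognition site from the
    background, giving fixtures full control over restriction geometry.
    The background is always scrubbed of every configured primer site.
    """
    rng = np.random.default_rng(seed)
    specs = sorted(insertions, key=lambda s: s.position)
    positions = [s.position for s in specs]
    if len(set(positions)) != len(positions):
        raise OverlappingInsertionsError("insertions at identical positions")
    for s in specs:
        if not 0 <= s.position <= background_length:
            raise ValueError(f"insertion {s.locus_id} outside the background")

    bg = list(background if background is not None
              else random_seq(rng, background_length, gc))
    if len(bg) != background_length:
        raise ValueError("explicit background length mismatch")
    # primer-site safety in the background
    for name in ("GAG", "ENV", "LTR5", "LTR3"):
        _scrub_pattern(rng, bg, template.primer_window(name))
    if clear_natural_sites:
        _scrub_pattern(rng, bg, enzyme.recognition)
    # planted restriction sites
    planted: list[tuple[int, int]] = []
    if site_plan:
        rec = enzyme.recognition.upper()
        for s in specs:
            plan = site_plan.get(s.locus_id)
            if not plan:
                continue
            for side, dist in plan.items():
                if side == "five":
                    start = s.position - dist - enzyme.cut_offset
                elif side == "three":
                    start = s.position + dist - enzyme.cut_offset
                else:
                    raise ValueError(f"unknown side {side!r} in site plan")
                if not 0 <= start <= background_length - len(rec):
                    raise ValueError(f"planted site for {s.locus_id} out of range")
                for p0, p1 in planted:
                    if start < p1 and start + len(rec) > p0:
                        raise ValueError("planted restriction sites overlap")
                bg[start:start + len(rec)] = list(rec)
                planted.append((start, start + len(rec)))

    # decoy recipes inserted like elements at free random positions
    items: list[tuple[int, str, object]] = [(s.position, "locus", s) for s in specs]
    taken = set(positions)
    for d in range(decoys):
        while True:
            pos = int(rng.integers(0, background_length + 1))
            if pos not in taken:
                taken.add(pos)
                break
        items.append((pos, "decoy", f"decoy{d:02d}"))
    items.sort(key=lambda t: t[0])

    bg_str = "".join(bg)
    parts: list[str] = []
    cursor = 0
    offset = 0
    truth_rows = []
    decoy_rows = []
    elements: dict[str, PlantedElement] = {}
    for pos, kind, payload in items:
        parts.append(bg_str[cursor:pos])
        offset += pos - cursor
        cursor = pos
        if kind == "decoy":
            dseq = make_sva_decoy(template, rng)
            parts.append(dseq)
            decoy_rows.append({"decoy_id": payload, "contig": contig,
                               "start": offset, "end": offset + len(dseq)})
            offset += len(dseq)
            continue
        spec: InsertionSpec = payload
        el = _element_for(spec, template, rng)
        if el is None:
            # pre-insertion allele: single copy of the target sequence
            parts.append(spec.tsd)
            start, end = offset, offset + len(spec.tsd)
            elements[spec.locus_id] = PlantedElement(
                locus_id=spec.locus_id, contig=contig, start=start, end=end,
                state="pre_insertion", subtype=None, tsd=spec.tsd,
                tsd2=spec.tsd, orientation=spec.orientation,
            )
            offset = end
        else:
            el = _orient(el, spec.orientation)
            parts.append(el.seq)
            start, end = offset, offset + len(el.seq)
            shift = lambda span: (start + span[0], start + span[1])
            elements[spec.locus_id] = PlantedElement(
                locus_id=spec.locus_id, contig=contig, start=start, end=end,
                state=spec.allelic_state, subtype=el.subtype, tsd=el.tsd,
                tsd2=el.tsd2, orientation=spec.orientation,
                ltr5_span=shift(el.ltr5),
                ltr3_span=shift(el.ltr3) if el.ltr3 else None,
                anchors={n: (start + a0, start + a1, s)
                         for n, (a0, a1, s) in el.anchors.items()},
            )
            offset = end
        pe = elements[spec.locus_id]
        truth_rows.append({
            "locus_id": pe.locus_id, "contig": contig, "start": pe.start,
            "end": pe.end, "state": pe.state,
            "subtype": pe.subtype if pe.subtype else "NA", "tsd": pe.tsd,
        })
    parts.append(bg_str[cursor:])

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    decoy_df = pd.DataFrame(decoy_rows, columns=["decoy_id", "contig", "start", "end"])
    genome_seq = "".join(parts)
    sim = SimGenome(contig=contig, seq=genome_seq, truth=truth,
                    elements=elements, decoys=decoy_df, template=template,
                    background=bg_str, enzyme=enzyme)
    _assert_decoy_safety(sim)
    return sim


def _assert_decoy_safety(sim: SimGenome) -> None:
    """No background or decoy region may contain a target-primer site."""
    for name in ("GAG", "ENV"):
        window = sim.template.primer_window(name)
        for pat in (window, revcomp(window)):
            hits = find_all(sim.background, pat)
            if hits:
                raise AssertionError(f"background contains {name} primer site")
            for pos in find_all(sim.seq, pat):
                inside = any(
                    e.start <= pos < e.end for e in sim.elements.values()
                )
                if not inside:
                    raise AssertionError(
                        f"{name} primer site outside planted elements at {pos}"
                    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    n_individuals: int
    allele_freqs: Mapping[str, Mapping[str, float]]  # locus -> state -> freq
    seed: int

    def __post_init__(self):
        for locus, freqs in self.allele_freqs.items():
            for st, f in freqs.items():
                if st not in STATES:
                    raise ValueError(f"unknown state {st!r} at {locus}")
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"frequency outside [0, 1] at {locus}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} do not sum to 1")


def build_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw diploid genotypes under Hardy-Weinberg from planted frequencies.

    Returns one row per individual per locus with columns hap1/hap2; the
    realized allele counts are recoverable by value counting.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for locus, freqs in spec.allele_freqs.items():
        states = sorted(freqs)
        p = np.array([freqs[s] for s in states])
        draws = rng.choice(len(states), size=(spec.n_individuals, 2), p=p)
        for i in range(spec.n_individuals):
            rows.append({
                "individual": f"ind{i:04d}", "locus_id": locus,
                "hap1": states[draws[i, 0]], "hap2": states[draws[i, 1]],
            })
    return pd.DataFrame(rows, columns=["individual", "locus_id", "hap1", "hap2"])


def realized_allele_freqs(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-locus realized allele frequencies of a drawn population."""
    rows = []
    for locus, sub in genotypes.groupby("locus_id"):
        alleles = pd.concat([sub["hap1"], sub["hap2"]])
        freqs = alleles.value_counts(normalize=True)
        for state, f in freqs.items():
            rows.append({"locus_id": locus, "state": state,
                         "freq": float(f), "count": int(round(f * len(alleles)))})
    return pd.DataFrame(rows, columns=["locus_id", "state", "freq", "count"])


# ---------------------------------------------------------------------------
# locus-level fixtures for genotyping
# ---------------------------------------------------------------------------

@dataclass
class LocusFixture:
    """Flanks plus per-state allele sequences for one polymorphic locus."""

    flank5: str
    flank3: str
    tsd: str
    template: ProviralTemplate
    subtype: str = "II"
    haplotypes: dict[str, str] = field(default_factory=dict)

    def haplotype(self, state: str) -> str:
        if state not in self.haplotypes:
            if state == "pre_insertion":
                allele = self.tsd
            elif state == "solo_ltr":
                el = make_solo_ltr(make_provirus(self.template, self.subtype, self.tsd))
                allele = el.seq
            elif state == "provirus":
                allele = make_provirus(self.template, self.subtype, self.tsd).seq
            else:
                raise ValueError(f"unknown state {state!r}")
            self.haplotypes[state] = self.flank5 + allele + self.flank3
        return self.haplotypes[state]


def make_locus_fixture(
    template: ProviralTemplate,
    tsd: str = "CATGT",
    flank_len: int = 400,
    subtype: str = "II",
    seed: int = 0,
) -> LocusFixture:
    rng = np.random.default_rng(seed)
    f5 = list(random_seq(rng, flank_len))
    f3 = list(random_seq(rng, flank_len))
    for name in ("GAG", "ENV", "LTR5", "LTR3"):
        _scrub_pattern(rng, f5, template.primer_window(name))
        _scrub_pattern(rng, f3, template.primer_window(name))
    return LocusFixture(flank5="".join(f5), flank3="".join(f3), tsd=tsd,
                        template=template, subtype=subtype)


# ---------------------------------------------------------------------------
# LTR families for phylogenetic simulations
# ---------------------------------------------------------------------------

def demo_genome(
    seed: int,
    background_length: int = 120_000,
    n_proviruses: int = 3,
    n_solos: int = 2,
    n_decoys: int = 2,
) -> SimGenome:
    """A reproducible mixed fixture: proviruses, solo LTRs and decoys with
    planted restriction sites 200-900 bp from each junction."""
    template = default_template(seed=seed)
    rng = np.random.default_rng(seed)
    n = n_proviruses + n_solos
    positions = np.sort(rng.choice(
        np.arange(5_000, background_length - 5_000), size=n, replace=False))
    tsds = ["CATGT", "AGGAGA", "TTCAG", "GATTA", "CCAAT", "TGGAC"]
    specs = []
    site_plan = {}
    for i, pos in enumerate(positions):
        state = "provirus" if i < n_proviruses else "solo_ltr"
        locus = f"locus{i:02d}"
        specs.append(InsertionSpec(
            locus_id=locus, position=int(pos), allelic_state=state,
            subtype="II" if i % 2 == 0 else "I", tsd=tsds[i % len(tsds)],
            ltr_divergence_time=float(rng.integers(0, 3_000_000))))
        site_plan[locus] = {"five": int(rng.integers(200, 900)),
                            "three": int(rng.integers(200, 900))}
    return build_genome(template, background_length, specs, decoys=n_decoys,
                        seed=seed, site_plan=site_plan)


def ltr_family_alignment(
    n_loci: int = 10,
    ltr_len: int = DEFAULT_LTR_LEN,
    seed: int = 0,
    intra_divergence: tuple[float, float] = (0.005, 0.02),
    ancestral_divergence: float = 0.03,
    ts_tv_ratio: float = 2.0,
    gc: float = 0.41,
) -> dict[str, str]:
    """Simulate 5'/3' LTR pairs of independently inserted proviral loci.

    Each locus ancestor derives from a family consensus by
    ``ancestral_divergence`` substitutions per site (pairwise inter-locus
    divergence is therefore about twice that); its two LTR copies then evolve
    independently, each to a per-copy divergence drawn uniformly from
    ``intra_divergence``.  Sequences are gap-free and mutually aligned by
    construction.  Taxon names: ``L<i>_5p`` / ``L<i>_3p``.
    """
    rng = np.random.default_rng(seed)
    consensus = random_seq(rng, ltr_len, gc)
    out: dict[str, str] = {}
    for i in range(n_loci):
        ancestor = mutate(rng, consensus,
                          n_sub=round(ltr_len * ancestral_divergence),
                          ts_tv_ratio=ts_tv_ratio)
        for side in ("5p", "3p"):
            div = rng.uniform(*intra_divergence)
            out[f"L{i:02d}_{side}"] = mutate(
                rng, ancestor, n_sub=round(ltr_len * div),
                ts_tv_ratio=ts_tv_ratio)
    return out
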