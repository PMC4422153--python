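"""Turning amplicons into verified locus calls and genotypes.

A junction call places an amplicon's flank portion in the genome and records
which side of the junction the element occupies.  Calls from the two assay
modes are merged into loci, target-site duplications are detected as direct
repeats anchored at the element boundaries, and the Type I/II subtype is read
from the presence or absence of the 292 bp pol-env diagnostic segment.
Locus genotyping mirrors the two-sided PCR design: a flank-primer pair (a+b)
resolves pre-insertion and solo-LTR alleles by product size, while a+GAG and
ENV+b junction products identify a full provirus whose a+b product is too
long to amplify.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .amplify import Amplicon, GapsConfig, normalize_mode
from .sequtils import find_all, revcomp
from .simulate import LocusFixture, ProviralTemplate

MIN_FLANK_BP = 20   # verification: mapped flanking sequence
MIN_LTR_BP = 10     # verification: LTR portion in the amplicon


@dataclass
class JunctionCall:
    """One mapped LTR-flank junction."""

    contig: str | None
    position: int | None      # genomic coordinate of the LTR-flank boundary
    element_side: str         # 'left' | 'right' of the junction
    mode: str
    flank_len: int
    ltr_len_in_amplicon: int
    ambiguous: bool
    amplicon: Amplicon

    @property
    def placed(self) -> bool:
        return self.position is not None

    @property
    def verified(self) -> bool:
        return (self.placed and not self.ambiguous
                and self.flank_len >= MIN_FLANK_BP
                and self.ltr_len_in_amplicon >= MIN_LTR_BP)


@dataclass
class TsdCall:
    seq5: str
    seq3: str
    length: int
    mismatches: int

    @property
    def matches(self) -> int:
        return self.length - self.mismatches

    def __str__(self) -> str:  # e.g. "CATGT" or "15/18"
        if self.mismatches == 0:
            return self.seq5
        return f"{self.matches}/{self.length}"


@dataclass
class LocusCall:
    locus_id: str
    contig: str
    junction5: int | None     # LTR edge on the element's left
    junction3: int | None
    state: str = "provirus"   # the assay only recovers proviral structures
    subtype: str = "undetermined"
    tsd: TsdCall | None = None
    verified: bool = False
    ambiguous: bool = False
    evidence: list[JunctionCall] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int] | None:
        """Outer TSD edges, when both junctions and a TSD are known."""
        if self.junction5 is None or self.junction3 is None:
            return None
        t = self.tsd.length if self.tsd else 0
        return (self.junction5 - t, self.junction3 + t)


def map_junction(
    amplicon: Amplicon,
    genome: Mapping[str, str],
    ltr_part_len: int,
    min_flank: int = MIN_FLANK_BP,
) -> JunctionCall:
    """Locate an amplicon's flank in the genome and return the junction.

    ``ltr_part_len`` — how many bases of LTR the assay design places at the
    amplicon's LTR end (nested-primer offset + primer length) — splits the
    amplicon into an LTR portion and a flank portion.  The flank is placed by
    exact search; multiple placements flag the call ambiguous (first position
    kept), zero placements leave it unplaced.
    """
    seq = amplicon.sequence
    ltr_part = min(ltr_part_len, len(seq))
    if amplicon.ltr_end == "right":
        flank = seq[:-ltr_part] if ltr_part else seq
        element_side = "right"
    else:
        flank = seq[ltr_part:]
        element_side = "left"
    contig_seq = genome[amplicon.contig]
    hits = find_all(contig_seq, flank) if flank else []
    if not hits:
        return JunctionCall(None, None, element_side, amplicon.mode,
                            len(flank), ltr_part, ambiguous=True,
                            amplicon=amplicon)
    position = hits[0] + len(flank) if element_side == "right" else hits[0]
    return JunctionCall(amplicon.contig, position, element_side,
                        amplicon.mode, len(flank), ltr_part,
                        ambiguous=len(hits) > 1, amplicon=amplicon)


def detect_tsd(
    five_flank_suffix: str,
    three_flank_prefix: str,
    min_len: int = 4,
    max_len: int = 30,
    max_mismatch_frac: float = 0.2,
) -> TsdCall | None:
    """Best direct repeat anchored at the element boundaries, or None.

    Candidate length L compares the last L bases upstream of the element with
    the first L bases downstream; the longest L whose mismatch fraction stays
    within ``max_mismatch_frac`` wins (anchoring makes the candidate per
    length unique, so no further tie-break is needed).
    """
    limit = min(max_len, len(five_flank_suffix), len(three_flank_prefix))
    for L in range(limit, min_len - 1, -1):
        a = five_flank_suffix[-L:]
        b = three_flank_prefix[:L]
        mm = sum(x != y for x, y in zip(a, b))
        if mm / L <= max_mismatch_frac:
            return TsdCall(seq5=a, seq3=b, length=L, mismatches=mm)
    return None


def _locate(query: str, target: str, max_edits: int):
    res = edlib.align(query, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


@dataclass(frozen=True)
class DiagnosticRef:
    """Reference for subtype classification: the pol-env boundary segment
    absent from Type I genomes plus short flanking anchor sequences."""

    segment: str
    anchor_left: str
    anchor_right: str

    @classmethod
    def from_template(cls, template: ProviralTemplate,
                      anchor_len: int = 40) -> "DiagnosticRef":
        diag = template.diagnostic
        i2 = template.internal_type2
        d0 = template.diag_start_internal
        return cls(segment=diag,
                   anchor_left=i2[d0 - anchor_len:d0],
                   anchor_right=i2[d0 + len(diag):d0 + len(diag) + anchor_len])


def classify_subtype(
    internal_sequence: str,
    template: "ProviralTemplate | DiagnosticRef",
    identity: float = 0.95,
) -> tuple[str, dict]:
    """Type II if the diagnostic pol-env segment is present (>= ``identity``
    over its full length), Type I if its flanking anchors are present but the
    segment is absent, undetermined otherwise (solo LTR, truncation).

    ``template`` may be a full :class:`ProviralTemplate` or a bare
    :class:`DiagnosticRef`.  The detail dict reports the measured deletion
    length for Type I calls.
    """
    ref = (template if isinstance(template, DiagnosticRef)
           else DiagnosticRef.from_template(template))
    diag = ref.segment
    k_diag = int(len(diag) * (1.0 - identity))
    hit = _locate(diag, internal_sequence, k_diag)
    if hit is not None:
        return "II", {"deletion": 0, "diag_edits": hit[2]}
    left, right = ref.anchor_left, ref.anchor_right
    k_anchor = max(1, len(left) // 10)
    lh = _locate(left, internal_sequence, k_anchor)
    rh = _locate(right, internal_sequence, k_anchor)
    if lh is None or rh is None:
        return "undetermined", {"reason": "diagnostic region not covered"}
    observed_gap = rh[0] - lh[1]
    if observed_gap > len(diag) // 2:
        return "undetermined", {"reason": "anchors too far apart",
                                "observed_gap": observed_gap}
    return "I", {"deletion": len(diag) - max(observed_gap, 0),
                 "observed_gap": observed_gap}


def merge_junctions(
    calls: Sequence[JunctionCall],
    merge_radius: int = 50,
    max_element_span: int = 12000,
) -> list[LocusCall]:
    """Group junction calls into loci.

    Same-side calls within ``merge_radius`` collapse into one junction;
    a left-of-element junction then pairs with the nearest right-of-element
    junction lying at most ``max_element_span`` downstream.
    """
    placed = [c for c in calls if c.placed]
    unplaced = [c for c in calls if not c.placed]

    def cluster(side: str) -> list[list[JunctionCall]]:
        cs = sorted((c for c in placed if c.element_side == side),
                    key=lambda c: (c.contig, c.position))
        groups: list[list[JunctionCall]] = []
        for c in cs:
            if (groups and groups[-1][0].contig == c.contig
                    and c.position - groups[-1][-1].position <= merge_radius):
                groups[-1].append(c)
            else:
                groups.append([c])
        return groups

    right_el = cluster("right")   # junction5: element to the right
    left_el = cluster("left")     # junction3: element to the left
    loci: list[LocusCall] = []
    used_left: set[int] = set()
    for g5 in right_el:
        j5 = g5[0].position
        contig = g5[0].contig
        best = None
        for idx, g3 in enumerate(left_el):
            if idx in used_left or g3[0].contig != contig:
                continue
            gap = g3[0].position - j5
            if 0 < gap <= max_element_span:
                if best is None or gap < best[1]:
                    best = (idx, gap)
        if best is not None:
            used_left.add(best[0])
            g3 = left_el[best[0]]
            loci.append(LocusCall(
                locus_id="", contig=contig, junction5=j5,
                junction3=g3[0].position, evidence=g5 + g3,
                ambiguous=any(c.ambiguous for c in g5 + g3)))
        else:
            loci.append(LocusCall(
                locus_id="", contig=contig, junction5=j5, junction3=None,
                evidence=g5, ambiguous=any(c.ambiguous for c in g5)))
    for idx, g3 in enumerate(left_el):
        if idx not in used_left:
            loci.append(LocusCall(
                locus_id="", contig=g3[0].contig, junction5=None,
                junction3=g3[0].position, evidence=g3,
                ambiguous=any(c.ambiguous for c in g3)))
    for c in unplaced:
        loci.append(LocusCall(locus_id="", contig=c.amplicon.contig,
                              junction5=None, junction3=None,
                              evidence=[c], ambiguous=True))
    loci.sort(key=lambda l: (l.contig, l.junction5 if l.junction5 is not None
                             else (l.junction3 or 0)))
    for i, locus in enumerate(loci):
        locus.locus_id = f"locus{i:03d}"
    return loci


def call_loci(
    amplicons: Sequence[Amplicon],
    genome: Mapping[str, str],
    config: GapsConfig,
    template: "ProviralTemplate | DiagnosticRef | None" = None,
    merge_radius: int = 50,
    max_element_span: int = 12000,
    tsd_params: dict | None = None,
) -> list[LocusCall]:
    """Full characterization: map junctions, merge, detect TSDs, classify."""
    tsd_params = tsd_params or {}
    max_tsd = tsd_params.get("max_len", 30)
    junctions = [
        map_junction(a, genome, config.ltr_part_length(a.mode))
        for a in amplicons
    ]
    loci = merge_junctions(junctions, merge_radius=merge_radius,
                           max_element_span=max_element_span)
    for locus in loci:
        if locus.junction5 is not None and locus.junction3 is not None:
            seq = genome[locus.contig]
            locus.tsd = detect_tsd(
                seq[max(locus.junction5 - max_tsd, 0):locus.junction5],
                seq[locus.junction3:locus.junction3 + max_tsd],
                **tsd_params)
            if template is not None:
                internal = seq[locus.junction5:locus.junction3]
                locus.subtype, _ = classify_subtype(internal, template)
        locus.verified = (
            locus.tsd is not None
            and all(c.verified for c in locus.evidence)
        )
    return loci


def loci_table(loci: Sequence[LocusCall]) -> pd.DataFrame:
    rows = []
    for l in loci:
        span = l.span
        rows.append({
            "locus_id": l.locus_id, "contig": l.contig,
            "start": span[0] if span else pd.NA,
            "end": span[1] if span else pd.NA,
            "junction5": l.junction5 if l.junction5 is not None else pd.NA,
            "junction3": l.junction3 if l.junction3 is not None else pd.NA,
            "n_junction_fragments": len(l.evidence),
            "sides": "+".join(sorted({c.mode for c in l.evidence})),
            "state": l.state, "subtype": l.subtype,
            "tsd": str(l.tsd) if l.tsd else "none",
            "verified": l.verified, "ambiguous": l.ambiguous,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

@dataclass
class LocusAssay:
    """Primer quartet and size expectations for genotyping one locus."""

    primer_a: str          # plus strand, upstream flank
    primer_b: str          # minus strand (given 5'->3'), downstream flank
    primer_gag: str        # minus strand within gag (5'->3')
    primer_env: str        # plus strand within env
    pre_insertion_size: int
    ltr_length: int
    tsd_length: int
    max_product: int = 3000
    size_tol: int = 25

    @property
    def solo_size(self) -> int:
        return self.pre_insertion_size + self.ltr_length + self.tsd_length


def virtual_pcr(seq: str, fwd_primer: str, rev_primer: str,
                max_len: int) -> list[int]:
    """Product lengths for a convergent primer pair on one haplotype.

    ``fwd_primer`` anneals to the plus strand and extends right;
    ``rev_primer`` (given 5'->3') anneals to the minus strand and extends
    left.  Every convergent pairing up to ``max_len`` is reported.
    """
    fwd_hits = find_all(seq, fwd_primer)
    rev_hits = [p + len(rev_primer) for p in find_all(seq, revcomp(rev_primer))]
    out = []
    for f in fwd_hits:
        for r in rev_hits:
            size = r - f
            if len(fwd_primer) <= size <= max_len:
                out.append(size)
    return sorted(out)


@dataclass
class GenotypeCall:
    individual: str
    locus_id: str
    alleles: tuple[str, str]           # per-haplotype states, 'no_call' allowed
    products: dict = field(default_factory=dict)

    @property
    def called(self) -> bool:
        return all(a in ("pre_insertion", "solo_ltr", "provirus")
                   for a in self.alleles)


def _haplotype_state(seq: str, assay: LocusAssay) -> str:
    ab = virtual_pcr(seq, assay.primer_a, assay.primer_b, assay.max_product)
    if ab:
        size = ab[0]
        if abs(size - assay.pre_insertion_size) <= assay.size_tol:
            return "pre_insertion"
        if abs(size - assay.solo_size) <= assay.size_tol:
            return "solo_ltr"
        return "no_call"
    g5 = virtual_pcr(seq, assay.primer_a, assay.primer_gag, assay.max_product)
    g3 = virtual_pcr(seq, assay.primer_env, assay.primer_b, assay.max_product)
    if g5 and g3:
        return "provirus"
    if g5 or g3:
        return "partial_provirus"
    return "no_call"


def genotype_locus(
    haplotypes: Sequence[str],
    assay: LocusAssay,
    individual: str = "ind0000",
    locus_id: str = "locus000",
) -> GenotypeCall:
    """Virtual-PCR genotype of one diploid individual at one locus."""
    if len(haplotypes) != 2:
        raise ValueError("diploid genotyping needs exactly two haplotypes")
    states = tuple(_haplotype_state(h, assay) for h in haplotypes)
    return GenotypeCall(individual=individual, locus_id=locus_id,
                        alleles=states)


def make_locus_assay(
    fixture: LocusFixture,
    a_offset: int = 60,
    b_offset: int = 60,
    primer_len: int = 20,
    max_product: int = 3000,
) -> LocusAssay:
    """Design flank primers for a locus fixture and measure the pre-insertion
    product size directly on the pre-insertion haplotype."""
    f5, f3 = fixture.flank5, fixture.flank3
    a = f5[len(f5) - a_offset:len(f5) - a_offset + primer_len]
    b_window = f3[b_offset - primer_len:b_offset]
    b = revcomp(b_window)
    gag = fixture.template.primer_seq("GAG")
    env = fixture.template.primer_seq("ENV")
    pre = fixture.haplotype("pre_insertion")
    sizes = virtual_pcr(pre, a, b, max_product)
    if len(sizes) != 1:
        raise ValueError("flank primers do not give a unique pre-insertion product")
    return LocusAssay(
        primer_a=a, primer_b=b, primer_gag=gag, primer_env=env,
        pre_insertion_size=sizes[0], ltr_length=len(fixture.template.ltr),
        tsd_length=len(fixture.tsd), max_product=max_product,
    )


def allele_frequency(calls: Sequence[GenotypeCall]) -> dict:
    """Per-state allele frequencies over called alleles; no-calls reported."""
    counts: dict[str, int] = {}
    no_calls = 0
    for c in calls:
        for a in c.alleles:
            if a in ("pre_insertion", "solo_ltr", "provirus"):
                counts[a] = counts.get(a, 0) + 1
            else:
                no_calls += 1
    total = sum(counts.values())
    freqs = {s: n / total for s, n in counts.items()} if total else {}
    return {"counts": counts, "frequencies": freqs,
            "n_called_alleles": total, "n_no_call": no_calls}
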