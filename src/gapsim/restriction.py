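"""Complete in-silico restriction digestion with coordinate-tracked fragments.

Digestion is "to completion": every occurrence of the recognition site on
either strand is cut at the top-strand cut position.  Fragments tile each
contig without gaps or overlaps, so concatenating fragment sequences always
reproduces the contig.  Linker ligation marks cut-site ends as competent for
linker-primed amplification and records the linker length used downstream in
amplicon size arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .sequtils import find_iupac, revcomp


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A single restriction enzyme: IUPAC recognition plus top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset must lie within the recognition site")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition.upper()) == self.recognition.upper()


#: AT^TAAT — the enzyme used throughout the protocol by default.
VSPI = RestrictionEnzyme("VspI", "ATTAAT", 2)


@dataclass
class Fragment:
    """A restriction fragment with genome coordinates and linker status."""

    contig: str
    start: int
    end: int
    sequence: str
    left_boundary: str = "cut_site"   # or "contig_end"
    right_boundary: str = "cut_site"
    linkered_left: bool = False
    linkered_right: bool = False
    linker_length: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


def cut_positions(seq: str, enzyme: RestrictionEnzyme = VSPI) -> list[int]:
    """Sorted, unique top-strand cut coordinates within ``seq``.

    Both strands are searched; palindromic sites cut once.  Cuts that would
    produce a zero-length fragment (at position 0 or len(seq)) are dropped.
    """
    seq = seq.upper()
    rec = enzyme.recognition.upper()
    cuts = {m + enzyme.cut_offset for m in find_iupac(seq, rec)}
    if not enzyme.is_palindromic:
        rc = revcomp(rec)
        cuts |= {
            m + len(rec) - enzyme.cut_offset for m in find_iupac(seq, rc)
        }
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(genome: Mapping[str, str], enzyme: RestrictionEnzyme = VSPI) -> list[Fragment]:
    """Completely digest every contig; fragments are returned in genome order."""
    fragments: list[Fragment] = []
    for contig, seq in genome.items():
        bounds = [0] + cut_positions(seq, enzyme) + [len(seq)]
        for i in range(len(bounds) - 1):
            start, end = bounds[i], bounds[i + 1]
            if start == end:
                continue  # empty contig
            fragments.append(
                Fragment(
                    contig=contig,
                    start=start,
                    end=end,
                    sequence=seq[start:end].upper(),
                    left_boundary="contig_end" if start == 0 else "cut_site",
                    right_boundary="contig_end" if end == len(seq) else "cut_site",
                )
            )
    return fragments


def ligate_linkers(
    fragments: list[Fragment],
    linker_length: int = 40,
    linker_contig_ends: bool = False,
) -> list[Fragment]:
    """Mark linker-ligated ends and store the linker length.

    Cut-site ends always receive a linker.  Contig ends are blunt genomic
    termini and are not linkered unless ``linker_contig_ends`` is set.
    """
    if linker_length < 0:
        raise ValueError("linker_length must be >= 0")
    out = []
    for frag in fragments:
        out.append(
            replace(
                frag,
                linkered_left=frag.left_boundary == "cut_site" or linker_contig_ends,
                linkered_right=frag.right_boundary == "cut_site" or linker_contig_ends,
                linker_length=linker_length,
            )
        )
    return out
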