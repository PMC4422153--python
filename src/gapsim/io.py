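"""File formats, run configuration and the end-to-end pipeline.

FASTA goes through Biopython; coordinates in BED6 output are 0-based
half-open, GFF3 is 1-based inclusive (conversion happens only here).
A run configuration is a YAML mapping carrying the enzyme, the primer set,
size parameters, the substitution rate and the caller thresholds; the seed
is mandatory so every stochastic stage is reproducible.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .amplify import Amplicon, GapsConfig, Primer, run_gaps
from .evolution import SubstitutionRate, estimate_age, pairwise_k2p
from .loci import DiagnosticRef, LocusCall, call_loci, loci_table
from .restriction import RestrictionEnzyme
from .sequtils import IUPAC_LETTERS

_VALID_CHARS = IUPAC_LETTERS | {"-"}


class FastaParseError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered name -> upper-case sequence mapping.

    Malformed headers or non-IUPAC characters raise
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].strip() else None
                if name is None:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                if name in seqs:
                    raise FastaParseError(f"{path}:{lineno}: duplicate record {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence before first header")
                up = line.upper()
                bad = set(up) - _VALID_CHARS
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)}")
                chunks.append(up)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_bed(rows: Sequence[dict], path) -> None:
    """BED6 from dicts with contig/start/end/name and optional score/strand."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in (
                r["contig"], r["start"], r["end"], r.get("name", "."),
                r.get("score", 0), r.get("strand", "."))) + "\n")


def truth_to_bed(truth: pd.DataFrame) -> list[dict]:
    return [
        {"contig": r.contig, "start": r.start, "end": r.end,
         "name": f"{r.locus_id}|{r.state}", "score": 0, "strand": "+"}
        for r in truth.itertuples()
    ]


def write_gff3(loci: Sequence[LocusCall], path, source: str = "gapsim") -> None:
    """One feature per mapped junction; 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            for side, pos in (("five_prime", locus.junction5),
                              ("three_prime", locus.junction3)):
                if pos is None:
                    continue
                attrs = ";".join([
                    f"ID={locus.locus_id}.{side}",
                    f"side={side}",
                    f"subtype={locus.subtype}",
                    f"tsd={locus.tsd if locus.tsd else 'none'}",
                    f"verified={str(locus.verified).lower()}",
                ])
                fh.write("\t".join([
                    locus.contig, source, "junction",
                    str(pos), str(pos + 1),   # 1-based inclusive, 2 bp window
                    ".", "+", ".", attrs]) + "\n")


def write_phylip(labels: Sequence[str], matrix, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for name, row in zip(labels, matrix):
            fh.write(name[:10].ljust(12)
                     + " ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class Thresholds:
    tsd_min: int = 4
    tsd_max: int = 30
    tsd_mismatch_frac: float = 0.2
    identity: float = 0.95
    merge_radius: int = 50
    max_element_span: int = 12000
    max_dist: int = 1000


@dataclass
class RunConfig:
    seed: int
    gaps: GapsConfig
    rate: SubstitutionRate = field(default_factory=SubstitutionRate)
    thresholds: Thresholds = field(default_factory=Thresholds)
    diagnostic: DiagnosticRef | None = None

    def to_yaml(self, path) -> None:
        g = self.gaps
        primers = {}
        for attr in ("target_5p", "target_3p", "nested_5p", "nested_3p"):
            p = getattr(g, attr)
            if p is not None:
                primers[attr] = {
                    "name": p.name, "sequence": p.sequence, "role": p.role,
                    "max_mismatches": p.max_mismatches,
                    "three_prime_exact": p.three_prime_exact,
                }
        doc = {
            "seed": self.seed,
            "enzyme": {"name": g.enzyme.name, "recognition": g.enzyme.recognition,
                       "cut_offset": g.enzyme.cut_offset},
            "primers": primers,
            "nested_5p_ltr_offset": g.nested_5p_ltr_offset,
            "nested_3p_ltr_offset": g.nested_3p_ltr_offset,
            "ltr_length": g.ltr_length,
            "linker_length": g.linker_length,
            "nested_linker_length": g.nested_linker_length,
            "size_window": list(g.size_window),
            "min_product": g.min_product,
            "max_first_round": g.max_first_round,
            "rate": {"mu": self.rate.mu, "sigma": self.rate.sigma},
            "thresholds": asdict(self.thresholds),
        }
        if self.diagnostic is not None:
            doc["diagnostic"] = asdict(self.diagnostic)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "seed" not in doc:
            raise ValueError("config must state a seed")
        enz = doc.get("enzyme", {})
        enzyme = RestrictionEnzyme(enz.get("name", "VspI"),
                                   enz.get("recognition", "ATTAAT"),
                                   enz.get("cut_offset", 2))
        primers = {}
        for attr, spec in doc.get("primers", {}).items():
            primers[attr] = Primer(
                name=spec["name"], sequence=spec["sequence"],
                role=spec.get("role", "target"),
                max_mismatches=spec.get("max_mismatches", 0),
                three_prime_exact=spec.get("three_prime_exact", 3))
        gaps = GapsConfig(
            enzyme=enzyme,
            target_5p=primers.get("target_5p"),
            target_3p=primers.get("target_3p"),
            nested_5p=primers.get("nested_5p"),
            nested_3p=primers.get("nested_3p"),
            nested_5p_ltr_offset=doc.get("nested_5p_ltr_offset", 0),
            nested_3p_ltr_offset=doc.get("nested_3p_ltr_offset", 0),
            ltr_length=doc.get("ltr_length", 968),
            linker_length=doc.get("linker_length", 40),
            nested_linker_length=doc.get("nested_linker_length", 25),
            size_window=tuple(doc.get("size_window", (100, 3000))),
            min_product=doc.get("min_product", 50),
            max_first_round=doc.get("max_first_round", 5000),
        )
        rate_doc = doc.get("rate", {})
        rate = SubstitutionRate(rate_doc.get("mu", 3.77e-9),
                                rate_doc.get("sigma", 1.33e-9))
        thr = Thresholds(**doc.get("thresholds", {}))
        diag = (DiagnosticRef(**doc["diagnostic"])
                if "diagnostic" in doc else None)
        return cls(seed=int(doc["seed"]), gaps=gaps, rate=rate,
                   thresholds=thr, diagnostic=diag)

    def config_hash(self) -> str:
        blob = json.dumps(self._canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def _canonical(self) -> dict:
        g = self.gaps
        return {
            "seed": self.seed,
            "enzyme": [g.enzyme.name, g.enzyme.recognition, g.enzyme.cut_offset],
            "primers": {a: getattr(g, a).sequence
                        for a in ("target_5p", "target_3p", "nested_5p", "nested_3p")
                        if getattr(g, a) is not None},
            "sizes": [g.linker_length, g.nested_linker_length,
                      list(g.size_window), g.min_product, g.max_first_round],
            "rate": [self.rate.mu, self.rate.sigma],
            "thresholds": asdict(self.thresholds),
            "diagnostic": (asdict(self.diagnostic)
                           if self.diagnostic is not None else None),
        }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    amplicons: list[Amplicon]
    loci: list[LocusCall]
    summary: pd.DataFrame
    dating: pd.DataFrame
    logs: dict[str, pd.DataFrame]


def run_pipeline(genome: Mapping[str, str], config: RunConfig,
                 template=None) -> PipelineResult:
    """Both assay modes, locus calling and inter-LTR dating in one pass."""
    amplicons: list[Amplicon] = []
    logs = {}
    for mode in ("five_prime", "three_prime"):
        amps, log = run_gaps(genome, config.gaps, mode)
        amplicons.extend(amps)
        logs[mode] = log
    thr = config.thresholds
    loci = call_loci(
        amplicons, genome, config.gaps,
        template=template if template is not None else config.diagnostic,
        merge_radius=thr.merge_radius,
        max_element_span=thr.max_element_span,
        tsd_params={"min_len": thr.tsd_min, "max_len": thr.tsd_max,
                    "max_mismatch_frac": thr.tsd_mismatch_frac})
    summary = loci_table(loci)
    dating_rows = []
    L = config.gaps.ltr_length
    for locus in loci:
        if locus.junction5 is None or locus.junction3 is None:
            continue
        seq = genome[locus.contig]
        ltr5 = seq[locus.junction5:locus.junction5 + L]
        ltr3 = seq[locus.junction3 - L:locus.junction3]
        if len(ltr5) != L or len(ltr3) != L:
            continue
        res = pairwise_k2p(ltr5, ltr3)
        age = estimate_age(res.d, config.rate)
        lo, hi, mean = age.in_mya()
        dating_rows.append({
            "locus_id": locus.locus_id, "divergence": res.d,
            "n_sites": res.n_sites, "age_mean_mya": mean,
            "age_low_mya": lo, "age_high_mya": hi,
        })
    dating = pd.DataFrame(dating_rows, columns=[
        "locus_id", "divergence", "n_sites", "age_mean_mya",
        "age_low_mya", "age_high_mya"])
    return PipelineResult(amplicons=amplicons, loci=loci, summary=summary,
                          dating=dating, logs=logs)


def write_pipeline_outputs(result: PipelineResult, config: RunConfig,
                           outdir) -> dict:
    """Write all stage outputs plus a machine-readable manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    amp_fa = outdir / "amplicons.fasta"
    write_fasta({a.id: a.sequence for a in result.amplicons}, amp_fa)
    amp_bed = outdir / "amplicons.bed"
    write_bed([{"contig": a.contig, "start": a.start, "end": a.end,
                "name": a.mode, "strand": "+"} for a in result.amplicons],
              amp_bed)
    calls_gff = outdir / "loci.gff3"
    write_gff3(result.loci, calls_gff)
    summary_tsv = outdir / "loci.tsv"
    result.summary.to_csv(summary_tsv, sep="\t", index=False)
    dating_tsv = outdir / "dating.tsv"
    result.dating.to_csv(dating_tsv, sep="\t", index=False)
    log_paths = {}
    for mode, log in result.logs.items():
        p = outdir / f"run_log_{mode}.tsv"
        log.to_csv(p, sep="\t", index=False)
        log_paths[mode] = p.name
    manifest = {
        "tool": "gapsim", "version": __version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "n_amplicons": len(result.amplicons), "n_loci": len(result.loci),
        "outputs": {
            "amplicons_fasta": amp_fa.name, "amplicons_bed": amp_bed.name,
            "loci_gff3": calls_gff.name, "loci_tsv": summary_tsv.name,
            "dating_tsv": dating_tsv.name, **log_paths,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
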