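"""Genome accessibility and recovery-rate arithmetic.

A proviral junction is recoverable when it lies within ``max_dist`` (default
1 kb) of a restriction cut on its flank side, no cut falls between the
target-primer site and the junction (which would strand the primer and the
linker on different fragments), and the predicted first-round and nested
product sizes pass the run's size filters.  The per-side geometry mirrors the
amplification arithmetic exactly, so accessibility flags agree with a full
assay run on the same genome.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .amplify import GapsConfig
from .restriction import cut_positions
from .simulate import PlantedElement, SimGenome

SIDES = ("five_prime", "three_prime")


def recovery_rate(n_detected: int, n_expected: int) -> int:
    """Recovered percentage, rounded to the nearest integer for display."""
    if n_expected == 0:
        raise ValueError("n_expected must be positive")
    if not 0 <= n_detected <= n_expected:
        raise ValueError("need 0 <= n_detected <= n_expected")
    return int(round(100.0 * n_detected / n_expected))


def _side_geometry(el: PlantedElement, mode: str) -> dict | None:
    """Genomic geometry of one assay side, oriented by the anchor strand."""
    target_name = "GAG" if mode == "five_prime" else "ENV"
    nested_name = "LTR5" if mode == "five_prime" else "LTR3"
    if target_name not in el.anchors or nested_name not in el.anchors:
        return None
    t0, t1, t_strand = el.anchors[target_name]
    n0, n1, _ = el.anchors[nested_name]
    flank_side = "left" if t_strand == "-" else "right"
    junction = el.start if flank_side == "left" else el.end
    return {"flank_side": flank_side, "junction": junction,
            "target": (t0, t1), "nested": (n0, n1)}


def accessibility(
    sim: SimGenome,
    config: GapsConfig,
    max_dist: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Per-side accessibility of every planted provirus, plus an aggregate.

    Returns a table with one row per provirus per side (distance to the
    nearest external cut, internal-truncation flag, predicted product sizes,
    the accessible verdict and its reason) and a summary dict with the
    accessible fraction and expected recovery percentage.  Loci whose primer
    sites cannot be located are reported undetermined.
    """
    cuts = np.array(cut_positions(sim.seq, config.enzyme))
    lo, hi = config.size_window
    rows = []
    for el in sim.elements.values():
        if el.state != "provirus":
            for mode in SIDES:
                rows.append({"locus_id": el.locus_id, "side": mode,
                             "distance": pd.NA, "truncated": pd.NA,
                             "accessible": False, "reason": "no_target_site"})
            continue
        for mode in SIDES:
            geom = _side_geometry(el, mode)
            if geom is None:
                rows.append({"locus_id": el.locus_id, "side": mode,
                             "distance": pd.NA, "truncated": pd.NA,
                             "accessible": False, "reason": "undetermined"})
                continue
            j = geom["junction"]
            t0, t1 = geom["target"]
            n0, n1 = geom["nested"]
            target, nested = config.primers_for(mode)
            # primer-site integrity at the annotated anchors
            windows_ok = (
                _window_matches(sim.seq, t0, t1, target.sequence)
                and _window_matches(sim.seq, n0, n1, nested.sequence)
            )
            if geom["flank_side"] == "left":
                ext = cuts[cuts <= j]
                cut = int(ext.max()) if ext.size else None
                dist = None if cut is None else j - cut
                truncated = bool(np.any((cuts > j) & (cuts < t1)))
                first_len = None if cut is None else (t1 - cut) + config.linker_length
                amp_len = None if cut is None else (n1 - cut) + config.nested_linker_length
            else:
                ext = cuts[cuts >= j]
                cut = int(ext.min()) if ext.size else None
                dist = None if cut is None else cut - j
                truncated = bool(np.any((cuts > t0) & (cuts < j)))
                first_len = None if cut is None else (cut - t0) + config.linker_length
                amp_len = None if cut is None else (cut - n0) + config.nested_linker_length
            if not windows_ok:
                accessible, reason = False, "primer_site_lost"
            elif cut is None:
                accessible, reason = False, "no_flanking_cut_site"
            elif truncated:
                accessible, reason = False, "internal_cut_truncation"
            elif dist > max_dist:
                accessible, reason = False, "beyond_max_dist"
            elif not config.min_product <= first_len <= config.max_first_round:
                accessible, reason = False, "first_round_size"
            elif not lo <= amp_len <= hi:
                accessible, reason = False, "outside_gel_window"
            else:
                accessible, reason = True, "accessible"
            rows.append({
                "locus_id": el.locus_id, "side": mode,
                "distance": dist if dist is not None else pd.NA,
                "truncated": truncated,
                "first_round_length": first_len if first_len is not None else pd.NA,
                "amplicon_length": amp_len if amp_len is not None else pd.NA,
                "accessible": accessible, "reason": reason,
            })
    report = pd.DataFrame(rows)
    pro = [e for e in sim.elements.values() if e.state == "provirus"]
    acc_any = acc_both = 0
    for el in pro:
        sub = report[report.locus_id == el.locus_id]
        flags = sub.accessible.tolist()
        acc_any += any(flags)
        acc_both += all(flags)
    n = len(pro)
    summary = {
        "n_proviruses": n,
        "n_accessible_any_side": acc_any,
        "n_accessible_both_sides": acc_both,
        "accessible_fraction": acc_any / n if n else float("nan"),
        "expected_recovery_percent": recovery_rate(acc_any, n) if n else float("nan"),
    }
    return report, summary


def _window_matches(seq: str, a0: int, a1: int, primer_seq: str) -> bool:
    from .sequtils import revcomp
    window = seq[a0:a1]
    return window == primer_seq or window == revcomp(primer_seq)


def recovered_sides(sim: SimGenome, amplicons) -> dict[tuple[str, str], bool]:
    """Which (locus, side) junctions are covered by at least one amplicon.

    A side counts as recovered when an amplicon spans its outer TSD edge,
    i.e. the product carries the complete junction into the flank.  Keyed by
    (locus_id, side) for every planted provirus; used to cross-check
    accessibility flags against a full assay run.
    """
    out: dict[tuple[str, str], bool] = {}
    for el in sim.elements.values():
        if el.state != "provirus":
            continue
        for mode in SIDES:
            geom = _side_geometry(el, mode)
            if geom is None:
                out[(el.locus_id, mode)] = False
                continue
            j = geom["junction"]
            if geom["flank_side"] == "left":
                hit = any(a.start <= j - 1 and a.end > j for a in amplicons
                          if a.contig == el.contig)
            else:
                hit = any(a.end >= j + 1 and a.start < j for a in amplicons
                          if a.contig == el.contig)
            out[(el.locus_id, mode)] = hit
    return out
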