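"""Primer-site search, suppression selectivity, nested enrichment, run logs."""
import numpy as np
import pytest

from gapsim.amplify import (GapsConfig, Primer, find_primer_sites, nested_pcr,
                            run_gaps, suppression_pcr)
from gapsim.restriction import Fragment, digest, ligate_linkers
from gapsim.sequtils import random_seq, revcomp
from gapsim.simulate import InsertionSpec, build_genome


def _primer(seq, **kw):
    return Primer(name="p", sequence=seq, **kw)


class TestFindPrimerSites:
    def test_unique_hit_and_absence(self, rng):
        seq = random_seq(rng, 300)
        primer = _primer(seq[100:120])
        hits = find_primer_sites(seq, primer)
        plus = [h for h in hits if h.strand == "+"]
        assert [h.start for h in plus] == [100]
        absent = _primer("TTTTTTTTTTGGGGGGGGGG")
        assert find_primer_sites("ACGT" * 50, absent) == []

    def test_minus_strand_detection(self, rng):
        seq = random_seq(rng, 300)
        primer = _primer(revcomp(seq[50:70]))
        hits = [h for h in find_primer_sites(seq, primer) if h.strand == "-"]
        assert [h.start for h in hits] == [50]

    def test_internal_mismatch_tolerance_and_three_prime_gate(self, rng):
        seq = random_seq(rng, 200)
        window = seq[80:100]
        internal_mm = window[:10] + ("A" if window[10] != "A" else "C") + window[11:]
        hits = find_primer_sites(seq, _primer(internal_mm, max_mismatches=1))
        assert any(h.start == 80 and h.mismatches == 1 for h in hits)
        # same mismatch budget, but the mismatch sits in the 3' 3-mer
        terminal_mm = window[:-1] + ("A" if window[-1] != "A" else "C")
        hits = find_primer_sites(seq, _primer(terminal_mm, max_mismatches=1))
        assert not any(h.start == 80 and h.strand == "+" for h in hits)

    def test_short_primer_requires_override(self):
        with pytest.raises(ValueError):
            _primer("ACGTACGT")
        assert len(_primer("ACGTACGT", allow_short=True)) == 8


def _linkered_fragment(seq, linker=40, left=True, right=True):
    return Fragment(contig="c", start=0, end=len(seq), sequence=seq,
                    linkered_left=left, linkered_right=right,
                    linker_length=linker)


class TestSuppressionPcr:
    def test_product_length_arithmetic(self, rng):
        # target site whose 5' end is 800 bp from the linkered left end
        flank = random_seq(rng, 800)
        window = random_seq(rng, 20)
        seq = flank + window + random_seq(rng, 200)
        primer = _primer(revcomp(window))  # minus strand: extends leftward
        prods = suppression_pcr([_linkered_fragment(seq)], primer)
        assert len(prods) == 1
        assert prods[0].length == 800 + 20 + 40
        assert prods[0].linker_end == "left"

    def test_no_target_site_is_suppressed(self, rng):
        frag = _linkered_fragment(random_seq(rng, 500))
        assert suppression_pcr([frag], _primer("GGGGGGAAAAAATTTTTTCC")) == []

    def test_unlinkered_end_blocks_product(self, rng):
        seq = random_seq(rng, 400)
        primer = _primer(revcomp(seq[300:320]))  # extends left
        frag = _linkered_fragment(seq, left=False)
        assert suppression_pcr([frag], primer) == []

    def test_first_round_ceiling(self, rng):
        seq = random_seq(rng, 6000)
        primer = _primer(revcomp(seq[5500:5520]))
        frag = _linkered_fragment(seq)
        assert suppression_pcr([frag], primer, max_first_round=5000) == []
        assert len(suppression_pcr([frag], primer, max_first_round=6000)) == 1


class TestNestedPcr:
    def test_oriented_ltr_site_required(self, rng):
        seq = random_seq(rng, 1000)
        target = _primer(revcomp(seq[800:820]))
        prods = suppression_pcr([_linkered_fragment(seq)], target)
        # LTR primer pointing away from the linker end is not retained
        wrong = _primer(seq[400:420])
        assert nested_pcr(prods, wrong) == []
        right = _primer(revcomp(seq[400:420]))
        amps = nested_pcr(prods, right)
        assert len(amps) == 1
        assert amps[0].length == 420 + 25
        assert amps[0].sequence == seq[:420]

    def test_size_window_discards(self, rng):
        seq = random_seq(rng, 4500)
        target = _primer(revcomp(seq[4300:4320]))
        prods = suppression_pcr([_linkered_fragment(seq)], target)
        ltr = _primer(revcomp(seq[3975:3995]))
        assert nested_pcr(prods, ltr, size_window=(100, 3000)) == []
        assert len(nested_pcr(prods, ltr, size_window=(100, 5000))) == 1


class TestRunGaps:
    def test_single_provirus_two_amplicons_across_modes(self, template):
        spec = InsertionSpec("L0", 15000, "provirus", tsd="CATGT")
        sim = build_genome(template, 30000, [spec], seed=7,
                           clear_natural_sites=True,
                           site_plan={"L0": {"five": 700, "three": 900}})
        cfg = GapsConfig.from_template(template)
        amps5, _ = run_gaps(sim.as_dict(), cfg, "5p")
        amps3, _ = run_gaps(sim.as_dict(), cfg, "3p")
        assert len(amps5) == 1 and len(amps3) == 1
        el = sim.elements["L0"]
        # 5' amplicon: cut -> nested window end; includes TSD + flank
        a5 = amps5[0]
        assert a5.start == el.start - 700
        assert a5.end == el.ltr5_span[0] + 40 + 20
        assert a5.length == (a5.end - a5.start) + 25
        a3 = amps3[0]
        assert a3.end == el.end + 900
        assert a3.sequence == sim.seq[a3.start:a3.end]

    def test_internal_cut_site_truncates_five_prime(self, template):
        spec = InsertionSpec("L0", 15000, "provirus", tsd="CATGT")
        sim = build_genome(template, 30000, [spec], seed=8,
                           clear_natural_sites=True,
                           site_plan={"L0": {"five": 700, "three": 900}})
        el = sim.elements["L0"]
        # plant a cut between the nested LTR window and the gag primer site
        pos = el.ltr5_span[0] + 500
        seq = sim.seq[:pos] + "ATTAAT" + sim.seq[pos + 6:]
        cfg = GapsConfig.from_template(template)
        amps5, log5 = run_gaps({sim.contig: seq}, cfg, "5p")
        assert amps5 == []
        assert (log5.outcome == "no_oriented_ltr_site").any()

    def test_solo_and_decoy_only_genome_yields_nothing(self, template):
        specs = [InsertionSpec(f"S{i}", 4000 + 4000 * i, "solo_ltr", tsd="CATGT")
                 for i in range(3)]
        sim = build_genome(template, 20000, specs, decoys=5, seed=9)
        cfg = GapsConfig.from_template(template)
        for mode in ("5p", "3p"):
            amps, _ = run_gaps(sim.as_dict(), cfg, mode)
            assert amps == []

    def test_size_window_monotonicity(self, demo):
        cfg = GapsConfig.from_template(demo.template)
        narrow, _ = run_gaps(demo.as_dict(), cfg, "5p")
        import dataclasses
        wide_cfg = dataclasses.replace(cfg, size_window=(50, 6000),
                                       max_first_round=8000)
        wide, _ = run_gaps(demo.as_dict(), wide_cfg, "5p")
        narrow_ids = {a.id for a in narrow}
        wide_ids = {a.id for a in wide}
        assert narrow_ids <= wide_ids

    def test_missing_primer_role_named_in_error(self, demo):
        cfg = GapsConfig(nested_5p=None, target_5p=None)
        with pytest.raises(ValueError, match="target"):
            run_gaps(demo.as_dict(), cfg, "5p")

    def test_amplicon_sequences_are_genome_substrings(self, demo):
        cfg = GapsConfig.from_template(demo.template)
        for mode in ("5p", "3p"):
            amps, _ = run_gaps(demo.as_dict(), cfg, mode)
            for a in amps:
                assert a.sequence == demo.seq[a.start:a.end]
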