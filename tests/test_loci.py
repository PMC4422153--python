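"""Junction mapping, TSD detection, subtype classification, genotyping."""
import numpy as np
import pytest

from gapsim.amplify import GapsConfig, run_gaps
from gapsim.loci import (allele_frequency, call_loci, classify_subtype,
                         detect_tsd, genotype_locus, make_locus_assay,
                         map_junction, merge_junctions, virtual_pcr)
from gapsim.sequtils import random_seq
from gapsim.simulate import (InsertionSpec, build_genome, make_locus_fixture,
                             make_provirus, make_solo_ltr)


@pytest.fixture(scope="module")
def called_fixture(template):
    """One provirus with both junctions accessible, fully characterized."""
    spec = InsertionSpec("L0", 15000, "provirus", subtype="I", tsd="CATGT",
                         ltr_divergence_time=1e6)
    sim = build_genome(template, 30000, [spec], seed=21,
                       clear_natural_sites=True,
                       site_plan={"L0": {"five": 600, "three": 800}})
    cfg = GapsConfig.from_template(template)
    amps = []
    for mode in ("5p", "3p"):
        a, _ = run_gaps(sim.as_dict(), cfg, mode)
        amps.extend(a)
    return sim, cfg, amps


class TestMapJunction:
    def test_round_trip_junctions_match_truth(self, called_fixture, template):
        sim, cfg, amps = called_fixture
        el = sim.elements["L0"]
        for a in amps:
            call = map_junction(a, sim.as_dict(), cfg.ltr_part_length(a.mode))
            assert call.placed and not call.ambiguous
            expected = el.junction5 if a.mode == "five_prime" else el.junction3
            assert call.position == expected

    def test_two_sides_merge_into_one_locus(self, called_fixture, template):
        sim, cfg, amps = called_fixture
        assert len(amps) == 2
        loci = call_loci(amps, sim.as_dict(), cfg, template=template)
        assert len(loci) == 1
        locus = loci[0]
        el = sim.elements["L0"]
        assert locus.span == (el.start, el.end)
        assert str(locus.tsd) == "CATGT"
        assert locus.subtype == "I"
        assert locus.verified

    def test_foreign_flank_is_unplaced_and_flagged(self, called_fixture):
        sim, cfg, amps = called_fixture
        import dataclasses
        foreign = dataclasses.replace(
            amps[0], sequence=random_seq(np.random.default_rng(0), 400))
        call = map_junction(foreign, sim.as_dict(), cfg.ltr_part_length("5p"))
        assert not call.placed and call.ambiguous

    def test_verification_gate_on_short_flank(self, called_fixture):
        sim, cfg, amps = called_fixture
        import dataclasses
        a = amps[0]
        # truncate so only 12 bp of flank remain ahead of the LTR portion
        ltr_part = cfg.ltr_part_length(a.mode)
        short = dataclasses.replace(a, sequence=a.sequence[-(ltr_part + 12):])
        call = map_junction(short, sim.as_dict(), ltr_part)
        assert call.flank_len == 12
        assert not call.verified


class TestDetectTsd:
    def test_planted_pentamer(self, rng):
        f5 = random_seq(rng, 60) + "CATGT"
        f3 = "CATGT" + random_seq(rng, 60)
        hit = detect_tsd(f5, f3)
        assert (hit.seq5, hit.length, hit.mismatches) == ("CATGT", 5, 0)

    def test_no_repeat_fixture(self):
        assert detect_tsd("A" * 40, "C" * 40) is None

    def test_degenerate_long_repeat_reported_as_fraction(self, rng):
        core = "GCTGGTGGGCGAGAAAAA"  # 18-mer
        mutated = core[:4] + "A" + core[5:9] + "T" + core[10:14] + "C" + core[15:]
        assert sum(a != b for a, b in zip(core, mutated)) == 3
        f5 = random_seq(rng, 40) + core
        f3 = mutated + random_seq(rng, 40)
        hit = detect_tsd(f5, f3)
        assert hit.length == 18 and hit.mismatches == 3
        assert str(hit) == "15/18"


class TestClassifySubtype:
    def test_type_ii_detected(self, template):
        subtype, detail = classify_subtype(template.internal_type2, template)
        assert subtype == "II" and detail["deletion"] == 0

    def test_type_i_reports_292_deletion(self, template):
        subtype, detail = classify_subtype(template.internal_type1, template)
        assert subtype == "I"
        assert detail["deletion"] == 292

    def test_solo_ltr_is_undetermined(self, template):
        solo = make_solo_ltr(make_provirus(template, "II", tsd="CATGT"))
        subtype, _ = classify_subtype(solo.seq, template)
        assert subtype == "undetermined"

    def test_diverged_type_ii_still_recognised(self, template, rng):
        from gapsim.sequtils import mutate
        noisy = mutate(rng, template.internal_type2, p_sub=0.02)
        subtype, _ = classify_subtype(noisy, template)
        assert subtype == "II"


@pytest.fixture(scope="module")
def assay_fixture(template):
    fixture = make_locus_fixture(template, tsd="CATGT", seed=31)
    return fixture, make_locus_assay(fixture)


class TestGenotyping:
    def test_het_provirus_pre_insertion(self, assay_fixture):
        fixture, assay = assay_fixture
        call = genotype_locus(
            [fixture.haplotype("provirus"), fixture.haplotype("pre_insertion")],
            assay)
        assert sorted(call.alleles) == ["pre_insertion", "provirus"]

    def test_homozygous_solo_product_size(self, assay_fixture):
        fixture, assay = assay_fixture
        solo = fixture.haplotype("solo_ltr")
        sizes = virtual_pcr(solo, assay.primer_a, assay.primer_b,
                            assay.max_product)
        assert sizes == [assay.pre_insertion_size + assay.ltr_length
                         + len(fixture.tsd)]
        call = genotype_locus([solo, solo], assay)
        assert call.alleles == ("solo_ltr", "solo_ltr")

    def test_provirus_solo_heterozygote_shows_both_signals(self, assay_fixture):
        fixture, assay = assay_fixture
        pro = fixture.haplotype("provirus")
        # a+b fails on the proviral haplotype, both junction products fire
        assert virtual_pcr(pro, assay.primer_a, assay.primer_b,
                           assay.max_product) == []
        assert virtual_pcr(pro, assay.primer_a, assay.primer_gag,
                           assay.max_product)
        assert virtual_pcr(pro, assay.primer_env, assay.primer_b,
                           assay.max_product)
        call = genotype_locus([pro, fixture.haplotype("solo_ltr")], assay)
        assert sorted(call.alleles) == ["provirus", "solo_ltr"]

    def test_destroyed_primer_site_gives_no_call(self, assay_fixture):
        fixture, assay = assay_fixture
        hap = fixture.haplotype("pre_insertion")
        broken = hap.replace(assay.primer_a, "A" * len(assay.primer_a))
        call = genotype_locus([broken, hap], assay)
        assert call.alleles[0] == "no_call"
        assert not call.called


class TestAlleleFrequency:
    def test_all_homozygous(self):
        from gapsim.loci import GenotypeCall
        calls = [GenotypeCall(f"i{k}", "L0", ("provirus", "provirus"))
                 for k in range(101)]
        out = allele_frequency(calls)
        assert out["frequencies"] == {"provirus": 1.0}

    def test_mixed_counts_match_arithmetic(self):
        from gapsim.loci import GenotypeCall
        alleles = ["provirus"] * 115 + ["pre_insertion"] * 87
        calls = [GenotypeCall(f"i{k}", "L0", (alleles[2 * k], alleles[2 * k + 1]))
                 for k in range(101)]
        out = allele_frequency(calls)
        assert out["counts"] == {"provirus": 115, "pre_insertion": 87}
        assert out["frequencies"]["provirus"] == pytest.approx(115 / 202)

    def test_no_calls_excluded_from_denominator(self):
        from gapsim.loci import GenotypeCall
        calls = [GenotypeCall("i0", "L0", ("provirus", "no_call")),
                 GenotypeCall("i1", "L0", ("pre_insertion", "pre_insertion"))]
        out = allele_frequency(calls)
        assert out["n_no_call"] == 1
        assert out["n_called_alleles"] == 3
        assert out["frequencies"]["pre_insertion"] == pytest.approx(2 / 3)

    def test_zero_called_alleles_explicit_empty(self):
        from gapsim.loci import GenotypeCall
        out = allele_frequency([GenotypeCall("i0", "L0", ("no_call", "no_call"))])
        assert out["frequencies"] == {} and out["n_no_call"] == 2
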