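"""Generator truth: element anatomy, LTR evolution, genomes, populations."""
import numpy as np
import pytest

from gapsim.simulate import (InsertionSpec, OverlappingInsertionsError,
                             PopulationSpec, build_genome, build_population,
                             default_template, evolve_ltr_pair,
                             make_provirus, make_solo_ltr,
                             realized_allele_freqs)


class TestTemplate:
    def test_invariants(self, template):
        template.validate()
        assert len(template.diagnostic) == 292
        assert len(template.internal_type2) - len(template.internal_type1) == 292
        assert len(template.ltr) == 968
        assert len(template.provirus_core("II")) == 9472

    def test_primer_orientation(self, template):
        from gapsim.sequtils import revcomp
        # minus-strand primers are the reverse complement of their window
        assert template.primer_seq("GAG") == revcomp(template.primer_window("GAG"))
        assert template.primer_seq("ENV") == template.primer_window("ENV")


class TestMakeProvirus:
    def test_type_ii_contains_diagnostic_once(self, template):
        el = make_provirus(template, "II", tsd="CATGT")
        assert el.seq.count(template.diagnostic) == 1

    def test_type_i_is_292_shorter_and_lacks_diagnostic(self, template):
        el1 = make_provirus(template, "I", tsd="CATGT")
        el2 = make_provirus(template, "II", tsd="CATGT")
        assert el2.length - el1.length == 292
        assert template.diagnostic not in el1.seq

    def test_tsd_copies_flank_element(self, template):
        el = make_provirus(template, "II", tsd="CATGT")
        assert el.seq.startswith("CATGT") and el.seq.endswith("CATGT")

    def test_long_tsd_needs_override(self, template):
        with pytest.raises(ValueError):
            make_provirus(template, "II", tsd="A" * 31)
        el = make_provirus(template, "II", tsd="A" * 31, allow_long_tsd=True)
        assert el.tsd == "A" * 31

    def test_degenerate_tsd_mismatches_planted(self, template, rng):
        el = make_provirus(template, "II", tsd="GCTGGTGGGCGAGAAAAA",
                           tsd_mismatches=3, rng=rng)
        diffs = sum(a != b for a, b in zip(el.tsd, el.tsd2))
        assert diffs == 3


class TestEvolveLtrPair:
    def test_time_zero_keeps_ltrs_identical(self, template):
        el = make_provirus(template, "II")
        out = evolve_ltr_pair(el, time_years=0.0, seed=1)
        s = out.seq
        assert s[slice(*out.ltr5)] == s[slice(*out.ltr3)]

    def test_expected_divergence_matches_poisson(self, template):
        # 968 sites/LTR, rate 3.77e-9, 1.06 My: expectation ~7.7 differences,
        # Poisson sd ~2.8; the mean over 200 seeds has SE ~0.2.
        el = make_provirus(template, "II")
        L = 968
        expected = 2 * L * 3.77e-9 * 1.06e6
        counts = []
        for seed in range(200):
            out = evolve_ltr_pair(el, 1.06e6, seed=seed)
            a = out.seq[slice(*out.ltr5)]
            b = out.seq[slice(*out.ltr3)]
            counts.append(sum(x != y for x, y in zip(a, b)))
        mean = np.mean(counts)
        se = np.sqrt(expected) / np.sqrt(200)
        assert abs(mean - expected) < 3 * se

    def test_infinite_ts_tv_gives_only_transitions(self, template):
        from gapsim.sequtils import TRANSITION
        el = make_provirus(template, "II")
        out = evolve_ltr_pair(el, 5e6, ts_tv_ratio=float("inf"), seed=3)
        for span in (out.ltr5, out.ltr3):
            before = el.seq[slice(*span)]
            after = out.seq[slice(*span)]
            for x, y in zip(before, after):
                if x != y:
                    assert y == TRANSITION[x]

    def test_protected_windows_do_not_mutate(self, template):
        el = make_provirus(template, "II")
        out = evolve_ltr_pair(el, 5e7, seed=4, protect_primer_sites=True)
        for name in ("LTR5", "LTR3"):
            a0, a1, _ = el.anchors[name]
            assert out.seq[a0:a1] == el.seq[a0:a1]


class TestSoloLtr:
    def test_breakpoint_zero_keeps_five_prime_ltr(self, template):
        el = evolve_ltr_pair(make_provirus(template, "II", tsd="CATGT"),
                             3e6, seed=5)
        solo = make_solo_ltr(el, breakpoint=0)
        assert solo.seq[slice(*solo.ltr5)] == el.seq[slice(*el.ltr5)]

    def test_breakpoint_end_keeps_three_prime_ltr(self, template):
        el = evolve_ltr_pair(make_provirus(template, "II", tsd="CATGT"),
                             3e6, seed=6)
        solo = make_solo_ltr(el, breakpoint=len(template.ltr))
        assert solo.seq[slice(*solo.ltr5)] == el.seq[slice(*el.ltr3)]

    def test_length_arithmetic(self, template):
        el = make_provirus(template, "II", tsd="CATGT")
        solo = make_solo_ltr(el)
        assert solo.length == len(template.ltr) + 2 * 5

    def test_single_ltr_input_rejected(self, template):
        solo = make_solo_ltr(make_provirus(template, "II"))
        with pytest.raises(ValueError):
            make_solo_ltr(solo)


class TestBuildGenome:
    def test_no_insertions_empty_truth(self, template):
        sim = build_genome(template, 5000, [], seed=1)
        assert sim.truth.empty
        assert len(sim.seq) == 5000

    def test_three_proviruses_in_truth(self, template):
        specs = [InsertionSpec(f"L{i}", 2000 + 3000 * i, "provirus", tsd="CATGT")
                 for i in range(3)]
        sim = build_genome(template, 12000, specs, seed=2)
        assert list(sim.truth.state) == ["provirus"] * 3
        # truth spans point at the real element sequence
        for el in sim.elements.values():
            assert sim.seq[el.start:el.start + 5] == "CATGT"

    def test_reconstruction_excising_planted_spans_recovers_background(self, template):
        specs = [InsertionSpec("L0", 2000, "provirus", tsd="CATGT"),
                 InsertionSpec("L1", 6000, "solo_ltr", tsd="GATTA")]
        sim = build_genome(template, 9000, specs, decoys=2, seed=3)
        spans = [(e.start, e.end) for e in sim.elements.values()]
        spans += [(r.start, r.end) for r in sim.decoys.itertuples()]
        seq = sim.seq
        for s, e in sorted(spans, reverse=True):
            seq = seq[:s] + seq[e:]
        assert seq == sim.background

    def test_determinism_byte_identical(self, template):
        specs = [InsertionSpec("L0", 1000, "provirus", tsd="CATGT",
                               ltr_divergence_time=2e6)]
        a = build_genome(template, 8000, specs, decoys=1, seed=9)
        b = build_genome(template, 8000, specs, decoys=1, seed=9)
        assert a.seq == b.seq
        assert a.truth.equals(b.truth)

    def test_overlapping_insertions_rejected(self, template):
        specs = [InsertionSpec("L0", 1000, "provirus"),
                 InsertionSpec("L1", 1000, "solo_ltr")]
        with pytest.raises(OverlappingInsertionsError):
            build_genome(template, 8000, specs, seed=1)

    def test_minus_orientation_round_trip(self, template):
        from gapsim.sequtils import revcomp
        spec = InsertionSpec("L0", 3000, "provirus", tsd="CATGT",
                             orientation="-")
        sim = build_genome(template, 8000, [spec], seed=4)
        el = sim.elements["L0"]
        core = sim.seq[el.junction5:el.junction3]
        assert revcomp(core) == template.provirus_core("II")

    def test_pre_insertion_plants_single_target_copy(self, template):
        spec = InsertionSpec("L0", 3000, "pre_insertion", tsd="CATGT")
        sim = build_genome(template, 8000, [spec], seed=5)
        el = sim.elements["L0"]
        assert sim.seq[el.start:el.end] == "CATGT"
        assert len(sim.seq) == 8005


class TestPopulation:
    def test_freq_one_gives_all_homozygotes(self):
        spec = PopulationSpec(20, {"L0": {"provirus": 1.0}}, seed=1)
        geno = build_population(spec)
        assert set(geno.hap1) == set(geno.hap2) == {"provirus"}

    def test_planted_frequency_recovered_over_seeds(self):
        # n=101, p=0.57: SE of the mean realized frequency over 500 seeds
        p, n, seeds = 0.57, 101, 500
        freqs = []
        for seed in range(seeds):
            spec = PopulationSpec(
                n, {"L0": {"provirus": p, "pre_insertion": 1 - p}}, seed=seed)
            geno = build_population(spec)
            alleles = list(geno.hap1) + list(geno.hap2)
            freqs.append(alleles.count("provirus") / len(alleles))
        se = np.sqrt(p * (1 - p) / (2 * n)) / np.sqrt(seeds)
        assert abs(np.mean(freqs) - p) < 3 * se

    def test_low_frequency_expected_count(self):
        # 2 x 101 x 0.035 ~ 7 solo alleles on average
        counts = []
        for seed in range(300):
            spec = PopulationSpec(
                101, {"L0": {"solo_ltr": 0.035, "provirus": 0.965}}, seed=seed)
            geno = build_population(spec)
            alleles = list(geno.hap1) + list(geno.hap2)
            counts.append(alleles.count("solo_ltr"))
        assert abs(np.mean(counts) - 2 * 101 * 0.035) < 0.5

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(10, {"L0": {"provirus": 1.2, "pre_insertion": -0.2}},
                           seed=0)

    def test_realized_freq_table(self):
        spec = PopulationSpec(50, {"L0": {"provirus": 0.5, "pre_insertion": 0.5}},
                              seed=3)
        table = realized_allele_freqs(build_population(spec))
        assert abs(table.freq.sum() - 1.0) < 1e-12
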