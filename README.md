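# gapsim

In-silico modelling of **GAPS** — genome-wide amplification of proviral
sequences — a suppression-PCR assay that selectively recovers full- and
near-full-length HERV-K(HML-2) proviruses from restriction-digested,
linker-ligated genomic DNA, together with the downstream analyses used to
characterize the recovered loci: target-site-duplication detection,
Type I/II classification by the 292 bp pol–env diagnostic segment,
provirus / solo-LTR / pre-insertion genotyping by virtual PCR, and
insertion dating from inter-LTR divergence with neighbor-joining/bootstrap
phylogenetics.

It is written for people who study endogenous retrovirus polymorphism:
the package generates synthetic genomes with planted proviruses, solo LTRs
and SVA-like decoys (with machine-readable truth), runs the whole assay on
them, and scores every stage exactly — so assay design questions ("what
does a different enzyme recover?", "which loci are invisible to a 1 kb
window?") can be answered before touching DNA.

## The model in brief

* **Digestion/ligation.** Complete digestion with one enzyme (default VspI,
  `AT^TAAT`); linkers on every cut-site end.
* **Suppression PCR.** A fragment amplifies iff a proviral *gag* (5′ assay)
  or *env* (3′ assay) primer lands inside it; the product runs to the
  linkered end. Everything else — background, solo LTRs, SVA-like elements —
  is suppressed.
* **Nested enrichment.** An LTR primer oriented toward the linker end
  shortens the product to an LTR–TSD–flank junction fragment; a gel size
  window (default 100–3,000 bp) is applied.
* **Calling.** Flanks are mapped back to the genome, 5′/3′ junctions are
  merged into loci, direct repeats are detected anchored at the element
  boundaries, and subtype is read from the diagnostic segment.
* **Dating.** For aligned LTR pairs, the Kimura two-parameter distance with
  pairwise deletion of gaps,

  d = −½·ln(1−2P−Q) − ¼·ln(1−2Q),

  is divided by the substitution rate μ = 3.77×10⁻⁹ ± 1.33×10⁻⁹ per site
  per year: the age range is (d/(μ+σ), d/(μ−σ)) and the point estimate is
  the mean of the bounds, reported in Mya.
* **Phylogenetics.** Unrooted Saitou–Nei neighbor joining over K2P
  distances, with column-resampling bootstrap support (default 500
  replicates); independently inserted proviruses show their 5′ and 3′ LTRs
  as supported sister taxa.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```bash
gaps simulate --seed 11 --out demo          # genome + truth + config
gaps pipeline --genome demo/genome.fasta --config demo/config.yaml --out demo/run
```

The demo genome (153,112 bp) carries three proviruses, two solo LTRs and
two SVA-like decoys. The pipeline recovers six junction amplicons, merges
them into three loci — the solo LTRs and decoys yield nothing, as the
suppression design intends — and writes `demo/run/loci.tsv`:

```
locus_id contig  start   end  junction5  junction3  n_junction_fragments                  sides    state subtype    tsd  verified
locus000   chr1  19142 28624      19147      28619                     2 five_prime+three_prime provirus      II  CATGT      True
locus001   chr1  29199 38391      29205      38385                     2 five_prime+three_prime provirus       I AGGAGA      True
locus002   chr1  81594 91076      81599      91071                     2 five_prime+three_prime provirus      II  TTCAG      True
```

Every span, TSD and subtype matches the generator's truth table exactly
(`demo/truth.tsv`). The dating report (`demo/run/dating.tsv`) gives each
locus's inter-LTR divergence and age:

```
locus_id  divergence  n_sites  age_mean_mya  age_low_mya  age_high_mya
locus000      0.0031      968        0.9411       0.6091        1.2731
locus001      0.0157      968        4.7501       3.0743        6.4258
locus002      0.0052      968        1.5716       1.0172        2.1261
```

Single comparisons work directly from sequences or FASTA:

```
$ gaps date --ltr5 l5.fa --ltr3 l3.fa
d=0.015679 (P=0.0103, Q=0.0052, n=968)
age = 4.75 Mya (3.07-6.43)
```

i.e. the two LTRs of `locus001` differ at ~1.6% of sites, dating its
insertion to roughly 4.8 Mya (3.1–6.4 Mya across the rate uncertainty).

Other subcommands: `gaps digest`, `gaps run --mode 5p|3p`, `gaps call`,
`gaps genotype`, `gaps tree`, `gaps sites`, `gaps coverage`. The same
functionality is available as a library (`import gapsim`).

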