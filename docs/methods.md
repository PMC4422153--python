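# Methods

`gapsim` models the selective recovery of full- and near-full-length
HERV-K(HML-2) proviruses from restriction-digested, linker-ligated genomic
DNA (the GAPS assay: genome-wide amplification of proviral sequences), and
the downstream characterization of the recovered loci.  This note records
the model, its assumptions, the parameters that matter, and the choices made
where the design was genuinely open.

## The assay model

A genome is digested to completion with a single restriction enzyme
(default VspI, `AT^TAAT`, top-strand cut two bases into the site).  Every
occurrence of the recognition site on either strand is cut; fragments tile
each contig exactly.  Double-stranded linkers are then ligated to every
cut-site terminus; native contig ends stay unlinkered.  Cut coordinates are
top-strand cut positions; the 2 nt 5' overhang the enzyme leaves means cut
coordinates on the reverse complement mirror up to that overhang.  This is
the only strand asymmetry in the model and it propagates nowhere (amplicon
content is unaffected at the scale of any downstream decision).

Suppression PCR is modelled as a hard selector rather than a kinetic
process: a fragment yields a first-round product if and only if a target
primer (gag-specific for the 5' assay, env-specific for the 3' assay)
anneals within it; the product runs from the target primer's 5' end to the
fragment's linkered end and gains the linker length.  Fragments without a
target site form suppressive stem-loops and contribute nothing — this is
what excludes solo LTRs and SVA-like elements, which carry LTR-derived
sequence but no gag/env.  Nested PCR keeps a product only when an LTR
primer anneals inside it oriented toward the linker end; the amplicon runs
from that primer to the linker end plus the nested linker primer length,
and a gel-window size filter is applied.

Primer annealing requires, by default, a perfect match with the 3'-terminal
3 bases exact; both tolerances are per-primer knobs (`max_mismatches`,
`three_prime_exact`).  Linkers are modelled by length only, since nothing
downstream depends on their sequence.  There is no polymerase error, no
stochastic dropout by default, and no band-intensity model.

Size parameters and defaults: first-round window 50–5,000 bp (a practical
PCR ceiling), nested gel window 100–3,000 bp, linker 40 nt, nested linker
primer 25 nt.  The gel window stands in for manual band excision and is
logged with every run.

## Synthetic genomes

The generator plants elements with full truth so every stage is scored
exactly.  A proviral template is 5'LTR–gag–pro–pol–env–3'LTR (defaults
968 bp LTRs, 9,472 bp total, region GC 0.41); the Type I variant deletes
the 292 bp segment spanning the pol–env boundary.  Elements are flanked by
target-site duplications (typically 4–6 bp; long degenerate repeats are
planted by mutating the downstream copy).  Solo LTRs keep both TSD copies
around a single 5'/3'-recombinant LTR (breakpoint configurable; breakpoint
0 retains the 5' LTR, matching the observation that a recently formed solo
LTR can be identical to a proviral 5' LTR).  SVA-like decoys contain LTR
sequence plus a GC-rich tract and are scrubbed of gag/env primer sites.

Backgrounds are i.i.d. nucleotides at GC 0.41 and are always scrubbed of
every configured primer site (asserted after generation), so selectivity
failures cannot hide in the scaffold.  Restriction geometry is controlled
two ways: `site_plan` writes a recognition site at an exact distance from a
chosen element edge, and `clear_natural_sites` removes chance occurrences
from the background first.  Coordinates are 0-based half-open; truth spans
run between the outer TSD edges.

LTR pairs diverge by independent per-site substitutions with a
transition/transversion ratio (default 2.0), no indels — deliberately the
same two-rate process the K2P estimator inverts.  `evolve_ltr_pair` uses a
per-copy rate: expected pairwise differences are `2 × L × rate × time`.
When elements are planted via `build_genome`, the nested-LTR primer windows
are excluded from mutation so that recall is purely a function of
restriction geometry; primer loss is still representable by disabling the
mask, and both the coverage module and the amplifier detect it.

Populations are diploid, drawn under Hardy–Weinberg from planted per-locus
allele frequencies with a mandatory seed.  The defaults used in tests
mirror the study's observed conditions (n = 101 individuals; proviral
allele frequency 0.57 at a dimorphic locus; solo-LTR frequency 0.035).

What the generator does not emulate — and hence what green tests do not
show about real data: sequence repeats and segmental duplications (flank
mapping here is near-unique by construction), nested insertions inside
proviruses, indel evolution, inter-LTR gene conversion, CpG rate
heterogeneity, and cell-line/DNA-quality artifacts.

## Locus calling

The caller works from amplicon sequences, not from generator truth.  The
assay design fixes how much LTR an amplicon carries (nested-primer offset
plus primer length); the remainder is flank and is placed in the genome by
exact search (a mismatch-tolerant search is a config knob for diverged
data).  Multiple placements flag the call ambiguous rather than dropping
it.  Same-side junctions within 50 bp merge; a left-of-element junction
pairs with the nearest right-of-element junction up to 12 kb downstream —
a radius alone cannot pair the two sides of a ~9.5 kb element, so the
pairing ceiling is the package's own addition and is configurable.

A locus is *verified* only when every junction call maps ≥ 20 bp of flank
and carries ≥ 10 bp of LTR, and a direct repeat is detected.  TSD detection
compares the flank suffix and prefix anchored at the element boundaries and
returns the longest repeat whose mismatch fraction is ≤ 0.2 — a threshold
that admits a 15/18 degenerate repeat (0.167) while rejecting noise;
anchoring makes the candidate per length unique, so no further tie-break is
needed.  Degenerate repeats print as `matches/length` (e.g. `15/18`).

Subtype: Type II requires the 292 bp diagnostic segment at ≥ 95% identity
over its full length (approximate search via edlib); Type I requires both
40 bp flanking anchors with the segment absent, and reports the measured
deletion; anything else (solo LTR, truncation) is undetermined.  The 95%
threshold tolerates simulated divergence; it is a config knob.

Genotyping follows the two-sided design: flank primers a+b amplify the
pre-insertion allele at its native size and the solo-LTR allele at
`pre + LTR + TSD`; a full provirus gives no a+b product (the ~9.5 kb
template exceeds the product ceiling, default the gel maximum) but yields
both a+GAG and ENV+b junction products.  One junction product without the
other is reported as `partial_provirus`, never forced to a genotype; a
destroyed primer site yields `no_call`, and no-calls are excluded from
allele-frequency denominators and counted.

## Coverage

A proviral junction is *accessible* when it lies within 1 kb (the assay's
stated design assumption) of an external cut on its flank side, no cut
falls between the target-primer site and the junction, both primer windows
are intact, and the predicted first-round and nested product lengths pass
the run's size filters.  The length predictions reuse the amplifier's
arithmetic verbatim, which is what makes the accessibility flags agree
exactly with a full run on the same genome (tested).  Recovery percentages
are displayed as integers; the raw ratio is retained.

## Distances, dating, trees

K2P: with transition proportion P and transversion proportion Q over the
compared sites, `d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)`.  Pairwise deletion drops,
per pair, exactly the columns where either sequence is gapped or ambiguous
(ambiguity codes are treated like gaps — the conservative reading).
Saturation (non-positive log arguments) and empty comparisons raise typed
errors rather than returning numbers.

Dating divides inter-LTR divergence by the substitution rate
μ = 3.77×10⁻⁹ per site per year with uncertainty σ = 1.33×10⁻⁹ (σ is read
as sharing μ's exponent): the reported range is `(d/(μ+σ), d/(μ−σ))` and
the point estimate is the mean of the two bounds — the reading that
reproduces the published age table exactly from its printed bounds.  Note
the convention this implies: μ calibrates the accumulation of the *pair*
divergence, so a locus of age t is simulated by mutating each copy with
per-site probability μ·t/2.  Ages are reported in Mya at 2–3 decimals; raw
years are retained.  Because the mean of the bounds exceeds d/μ whenever
σ > 0 (Jensen), parameter-recovery checks use σ = 0.

Neighbor joining is Saitou–Nei with two deterministic rules: Q-criterion
ties break toward the pair lowest in node-creation order, and negative
branch lengths are clamped to zero with a warning.  The tree is unrooted
(trifurcating virtual root).  Bootstrap resamples alignment columns with
replacement, rebuilds NJ from K2P pairwise-deletion distances per
replicate, and reports per-bipartition support as the percentage of
completed replicates; replicates with saturated or undefined distances are
skipped and counted.  A single seed drives all replicates.

Variable-site classification treats gaps/ambiguities as missing: a column
is parsimony-informative when at least two states each occur in at least
two sequences; variable but not informative is a singleton.  Positions are
reported 1-based.

The pairwise global aligner (Needleman–Wunsch, match 1 / mismatch −1 /
gap −2, traceback preferring diagonal, then gap-in-second, then
gap-in-first) exists to align LTR pairs before K2P when they are not
already positionally aligned; simulated pairs are gap-free so it is exercised
mainly by its brute-force oracle tests.

## Problem sizes used in the checks

The shipped checks run on desk-scale simulations chosen to make each
property measurable: demo genomes of ~120–360 kb with 1–26 planted
elements; 10-locus LTR families (20 × 968 bp alignments) with 500 bootstrap
replicates; 200 seeded populations of 25 diploid individuals for genotype
round-trips; 500 replicates for rate-recovery.  The study-scale counts
(145 humans, 15 loci from 18 junction fragments) are emulated structurally,
not reproduced numerically.

## Known limitations

Complete digestion only (a partial-digestion hook exists but is off);
single enzyme per run — broader coverage is explored by re-running with a
different enzyme config, not mixed digests; no thermodynamic primer model;
no gene-conversion simulator between LTRs (its signature — homogenised
pairs, anomalous sister grouping — is analysed descriptively via
variable-site classification); flank mapping assumes near-unique flanks;
circular contigs unsupported.
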