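# Methods

## Study design being modelled

The pipeline targets the standard seed-irradiation design in a selfing
diploid: dry seeds receive a single acute dose (here 250 Gy gamma rays
or 30 Gy carbon ions, both near LD30 for rice), surviving M1 plants
are selfed for four rounds, and each M5-derived line is sequenced as a
bulk of more than 20 M6 seedlings at roughly 30× so that allele
frequencies in the reads reflect the *zygosity of the M5 parent*: a
homozygous mutation appears at VAF ≈ 1, a heterozygous one — whose
selfed offspring are ¼ wild type, ½ het, ¼ hom — at VAF ≈ ½.

## Candidate filtering

Criteria are applied in a fixed order so each record receives exactly
one disposition: depth window → support fraction → cross-line
uniqueness → VAF confidence. Conventions, pinned by unit tests:

| quantity | rule | boundary behaviour |
|---|---|---|
| depth | more than 5 and less than 100 reads | 5 fails, 6 passes, 99 passes, 100 fails |
| support | ≥ 30% of reads | 0.30 inclusive (observationally irrelevant after the 40% gate) |
| uniqueness | exact (chrom, pos, ref, alt) in one line only | 2+ lines → all records fail as shared |
| confidence | VAF ≥ 40% | 0.40 inclusive |
| zygosity | hom if VAF > 75% | 0.75 exactly → heterozygous |

Indel representations are *not* left-aligned before the uniqueness
test; the synthetic generator emits one canonical anchored
representation, and real inputs are expected normalised upstream.

## Mendelian selfing model

Per selfing round, an unfixed mutation transitions het → {¼ lost, ½
het, ¼ hom}; lost/hom are absorbing. Closed form at generation k
(induced at m): p_het = (½)^(k−m), p_hom = p_lost = (1 − p_het)/2.
The closed form is verified in tests against an independent exact
per-round enumeration (fractions, no floats) and against the
stochastic transmitter at n = 10 000 (3-SE agreement).

Expected homozygosity among detectable (carrier) mutations at M5 is
p_hom/(p_hom + p_het) = 15/17 ≈ 88.2%. Some field reports instead use
a fixed 85.0% expectation whose derivation is not standard; both modes
are exposed (`expected_hom_fraction_override`, config
`homozygosity_mode: fixed`) and the Mendelian value is the default.
Under the pure Mendelian model, back-estimating from 86.7%
homozygosity of 81.1 mutations at M5 gives ≈ 112.6 expected M2
mutations — close to, but not identical with, figures produced by the
fixed-85% convention; the package does not attempt to reconcile the
two.

## Spectrum classification

SBS classes are strand-collapsed by orienting the reference base to a
purine, giving the six canonical classes; AT>GC and GC>AT are
transitions. Indel size is len(alt) − len(ref) of anchored VCF
alleles; |size| ≥ 100 bp routes to SV accounting. SV breakpoint events
whose breakpoints fall on one chromosome within a proximity window
merge into a single *complex* call; the two junction records of one
reciprocal exchange merge into a single translocation call. The
default window is 1 Mb — no numeric rule exists in the field, only
worked examples where the clustered double-strand breaks of one
particle traversal lie within a local region; the merge decision is
insensitive to the exact value across orders of magnitude for
realistic event densities. Every call counts as one SV regardless of
its constituent count.

## Rates and effectiveness

The headline rate divides the mean per-line mutation count by the
*across-line average* callable length (bases at ≥ 5×); per-line
callable lengths are carried for diagnostics only. With the published
351.4 Mb average this reproduces the gamma group's 23.1 × 10⁻⁸/bp
exactly; for the carbon-ion group the convention yields 18.4 ± 2.9
where the original report prints 18.3 ± 3.4, indicating that report
used per-line callable lengths for that cell — the difference is a
reporting convention, not a model disagreement, and only the gamma
cell is asserted in tests. Rates are reported to one decimal in
10⁻⁸/bp and effectiveness (rate/dose) in 10⁻⁹/bp/Gy.

## Group statistics

Summary spreads are **population** standard deviations (divisor n):
this is what reproduces the published ±3.0 (gamma SBS) and ±5.4
(gamma Total), where sample SDs give 3.3/5.9. The t-test is the
pooled (Student) two-sided form with df = nA+nB−2, using sample
variances as the statistic requires; Welch is available by flag.
Percentage make-up ("ratio") cells are computed per line and then
averaged; their published spreads (e.g. ±4.3 for gamma SBS) match
neither population (4.6) nor sample (5.0) SD of the per-line
percentages, so ratio spreads are reported under the population-SD
convention and not asserted against the printed values. Fisher's
exact test (two-sided, hypergeometric) and the df-1 chi-square
goodness-of-fit against an expected homozygous fraction round out the
battery; Fisher and the pooled t are cross-checked in tests against
full enumeration and a closed-form computation respectively.

## Synthetic data generator

The generator is first-class, tested code; its defaults *are* the
study conditions: 7 lines per group, Poisson per-line counts with
means 57.0/17.7/5.9/0.6 (gamma) and 43.7/13.6/5.3/2.0 (C-ion),
selfing M1→M5, bulks of 24 seedlings, Poisson(30) depth, 0.002
symmetric per-base error, 50 shared background variants and 5 low-VAF
artifacts per line.

Class make-up tables honour the published constraints and fill the
remainder with realistic mass chosen once: GC>AT at 43.0%/46.7%,
transition fraction 0.615 (Ts/Tv ≈ 1.6), deletion:insertion mass
matching the count means (~3:1), the +1…−4 bp band holding ~70%/~60%
of small indels with a long deletion tail to −80 bp. Gamma SVs are
large insertions and reciprocal translocations only; carbon-ion SVs
include deletions, duplications, inversions and 15% complex events of
2–3 clustered sub-events within ~50 kb — only the high-LET group
produces complex SVs, mirroring the multi-DSB footprint of particle
tracks.

Read evidence is simulated at the variant-record level:
alt ~ Binomial(depth, f(1−e) + (1−f)e) with f the bulk allele
frequency (1 for hom; the realised seedling-bulk mean, expectation ½,
for het). Background variants are emitted homozygous and identically
in every line — exactly what the cross-line uniqueness criterion
removes — and are placed away from induced-mutation loci so record
keys stay unique. Artifacts are clamped below 40% VAF at depth ≥ 6, so
their rejection tests the VAF gate rather than the depth window.

What the generator does **not** emulate: read sequences and alignment
(no FASTQ; mapping artifacts, repeat regions and indel-representation
ambiguity are absent), chimeric M1 plants (one genetically effective
cell per line is assumed), SV transmission bias/lethality, linkage
between nearby mutations, and depth heterogeneity beyond Poisson.
Passing tests therefore demonstrate correctness of the *pipeline
logic* under the stated statistical model, not robustness to raw-read
pathologies.

The toy genome defaults to 2 × 400 kb with 60 non-overlapping
two-exon genes (canonical GT..AG introns, ATG…stop ORFs, alternating
strands, GC 0.44); per-bp rates computed on it are therefore ~3 orders
above field values, by construction — rate *logic* is exercised on the
packaged 351.4 Mb figure instead. Tests and the acceptance script use
desk-scale sizes chosen as the package's own defaults: 200 (tests) or
100 (acceptance script) lines for 3-SE spectrum recovery, 10 000
mutations for transmission marginals, 7 lines for filter metrics.

## Impact annotation

Only the rules relevant to the tallies are implemented: within a
transcript (5′UTR–3′UTR) a variant "affects" the gene; CDS SBSs are
translated strand-aware into nonsense/missense/synonymous; CDS indels
are frameshift unless size ≡ 0 (mod 3); hits on the canonical 2-base
splice dinucleotides are splice-site loss; SV breakpoints inside a
gene body, or deletions overlapping it, truncate it. High impact =
nonsense, splice-site loss, frameshift, truncation; moderate =
missense, inframe indel. Design choices made where the rules are
silent: start-codon loss scores as missense-like (moderate); a gene
copied whole inside a duplication is affected but not truncated
(low/other, effect `whole_gene_duplication`); translocation junctions
inside genes truncate. A gene counts once per line, most severe
impact winning; small-mutation and SV origins are tallied separately
so SV-driven truncation bursts (8–21 genes from one large deletion)
remain visible.

## Numerical conventions and degenerate inputs

Coordinates are 1-based fully closed (converted only at BED
boundaries). VAF at depth 0 is an error in the API and reported as 0
for fail-depth records. Zero transversions make Ts/Tv an error rather
than infinity; zero pooled variance with unequal means is a t-test
error (equal means return t = 0, p = 1). Probability tables must sum
to 1 within 1e-9. All simulation randomness flows from a single
`numpy.random.default_rng` seed; fixed seeds give byte-identical
outputs (tested).

## Known limitations

Cross-line uniqueness uses exact allele matching, so differently
normalised representations of the same indel would evade the shared
filter on real data. The filter's recall on heterozygous M5 sites is
intentionally < 1 (binomial sampling puts some true hets below 40%
VAF), matching the conservative design of the original criteria. The
comparison of only two groups is hard-wired into the significance
marking (first vs second group); summaries themselves handle any
number of groups.
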