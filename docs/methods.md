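# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions that make runs reproducible.

## Study design and estimand

The package analyses retrospective case/control panels: per cohort, a fixed
number of cases and controls, genotyped at biallelic SNPs over one genomic
region. Under case/control sampling the odds ratio — not the risk ratio —
is the recoverable effect measure, which is why every association stage is
a logistic regression and why the synthetic generator fills case/control
quotas by rejection sampling rather than sampling a population.

Coordinates are 1-based inclusive throughout (BED input is converted at the
boundary: BED `s e` becomes `[s+1, e]`). The minor allele is defined on the
pooled sample of a panel, ties broken by the alphabetically later allele,
and is recomputed whenever a panel is split by population — so a
population-stratified MAF may legitimately exceed 0.5 and is reported
unclamped. Missing genotypes are excluded pairwise from frequencies and
regressions; no imputation is performed. Samples of unknown sex are dropped
from any fit that adjusts for sex.

## Per-SNP association

Additive coding (0/1/2 minor alleles), Newton-IRLS maximum likelihood
(via statsmodels), Wald z-tests, convergence at log-likelihood change
< 1e-8 or 50 iterations. 95% CIs use the multiplier 1.959964. The joint
("meta") analysis is a single pooled regression with sex and
population-indicator covariates (reference level: alphabetically first
label, for determinism); a fixed-effect inverse-variance combiner over
per-cohort fits is provided as an independent cross-check, not as the
primary route. Conditional scans add lead-SNP dosages as covariates; a
test SNP perfectly collinear with a conditioning SNP (r² = 1) is flagged
with p = NaN rather than raised, because that outcome is informative in a
conditional analysis, while collinearity among nuisance covariates raises
an error naming the offending columns. Non-convergence with |log OR| > 15
is reported as separation (p = NaN).

QC keeps variants with pooled MAF > 0.01 and exact Hardy–Weinberg p > 1e-4
in controls (the conventional pre-imputation filters). The HWE test is the
two-sided exact test: conditional on the allele counts, it sums the
probabilities of all heterozygote counts no more likely than the observed
one; monomorphic sites return p = 1 by convention.

## EM phasing

For a window of L ≤ 25 SNPs the hidden variable per individual is the
ordered haplotype pair. Individuals are grouped by genotype pattern; for a
pattern, each compatible first haplotype determines the second at all
non-missing sites, so pair enumeration is linear in the number of
compatible haplotypes (times 2^m for m in-window missing sites).
Initialisation is the deterministic product of single-SNP allele
frequencies; no random restarts are used, so a run is a pure function of
its inputs. Haplotypes below the frequency floor (default 0.01, a standard
haplotype-test default; the rarest reported haplotype in the reference
analysis is 0.029) are pruned between iterations with mass renormalised —
but only after a 5-iteration burn-in, because under the product
initialisation the first E-step spreads mass thinly over many spurious
haplotypes and immediate pruning can discard genuine rare ones.
Convergence: max frequency change < 1e-10, cap 1000 iterations. The
per-iteration log-likelihood trace is retained so tests can assert EM
monotonicity. Individuals with every window genotype missing are excluded
and reported. Reported haplotypes are sorted by frequency, ties broken by
allele-string lexicographic order.

Two-locus LD uses the same EM collapsed to the 3×3 genotype table (only
the double heterozygote is ambiguous): D = p_AB − p_A·p_B, D′ = D over its
margin-constrained maximum, r² = D²/(p_A p_a p_B p_b).

## Haplotype blocks

The block rule is the Gabriel confidence-interval method with the common
tooling defaults, since the reference analysis does not state its block
algorithm: the |D′| 90% CI is obtained by profiling the genotype-table
likelihood over a 101-point |D′| grid with allele frequencies fixed at
their MLEs and reading the 0.05/0.95 brackets of the normalised curve. A
pair is in strong LD when lower ≥ 0.70 and upper ≥ 0.98, shows strong
recombination when upper < 0.90, and is informative if either. A candidate
block needs a strong end pair and ≥ 95% strong among its informative
pairs; blocks are accepted greedily, longest bp span first,
non-overlapping. Monomorphic SNPs are ignored. Blocks wider than the
25-SNP enumeration guard are phased on the 25 SNPs nearest the anchor.

## Haplotype association and fine-mapping

Each haplotype at or above the floor is tested one-vs-rest with its
expected copy count (posterior dosage) as predictor — dosage coding is
stable under phase uncertainty and per-individual dosages always sum to 2.
Case- and control-stratum frequencies are re-estimated by running the EM
within each stratum, so the reported stratified frequencies are
within-stratum maximum-likelihood estimates rather than dosage averages
(the two agree within ~0.005 on simulated data; tests assert this).

The population gate includes a cohort iff its p-value at the anchor SNP is
below round(α/k, 3) — the rounding reproduces the conventional printed
threshold 0.05/6 → 0.008 exactly. The strict core is
[max of block starts, min of block ends] over gated cohorts' top blocks,
with member SNPs those inside the interval shared by all blocks. A
consensus mode extends the strict core outward SNP-by-SNP while every top
haplotype covering the flanking SNP carries the same allele; it documents
the behaviour needed to grow a core beyond the smallest block and is not
the default, because strict intersection is the only variant of the
procedure that is fully determined by the inputs. When the gate leaves a
single cohort, the pipeline uses that cohort's top block as the core (the
intersection of a singleton); `core_intersection` itself requires ≥ 2.

Protective/risk designation takes the two most frequent core haplotypes
and requires opposite OR directions, erroring rather than guessing
otherwise. A SNP is differentiating iff the protective haplotype carries
its minor allele and the risk haplotype its major allele; the refined
region spans the flagged SNPs. Interval spans in kb are truncated (not
rounded) to one decimal, matching the reporting convention of the block
tables (e.g. 53 780 bp → 53.7).

## Annotation

LD proxies are panel variants with EM r² ≥ 0.9 to the anchor. Feature
overlap is 1-based inclusive; a feature's class is its BED label prefix
before the first colon (`DNase:GM12878` → `DNase`). Motif scores are log₂
likelihood ratios against the background base distribution, with a 1e-3
pseudo-count applied at PWM load so no entry is zero; the best placement
over all offsets covering the SNP and both strands is chosen independently
for the reference and alternative alleles (max aggregation, the common
motif-break convention), and delta = best-alt − best-ref. The minus strand
is scored by reverse-complementing the matrix and its background, which is
identical to scoring the reverse-complemented window. Ranking is by
(distinct feature classes hit, max |delta|, position) — a total order, so
input permutation cannot change the output.

## Synthetic cohorts

`default_scenario(scale)` emulates the reference six-cohort study: cohort
sizes are `scale` × (UK 7728/8274, Italy 1486/1270, Netherlands 1150/1173,
Spain 1131/662, Poland 521/541, India 497/736; cases/controls), 14 SNPs
over chr3:188116907–188121019, and a four-haplotype pool whose per-cohort
frequencies are the published control-stratum values (renormalised to sum
to 1). The protective haplotype CCGATCTGGC**G**CAT is causal with
β = log 0.75 in the four European cohorts; Poland and India are modelled
as null cohorts carrying the combined-analysis control frequencies, since
their haplotype frequencies were never published and their top signals
point the opposite way. Five SNP positions are published anchors
(rs7634898, rs6790260, rs4686484, rs2030519, rs12634152); the other nine
are synthetic, order-preserving interpolations between the anchors, so all
derived interval arithmetic (2.8 kb refined span, 4.1 kb core) is exact
while individual interior positions are placeholders.

Generator model: two haplotypes i.i.d. from the cohort's pool (no
recombination — the region is a single LD block by construction), sex
Bernoulli(0.5), disease probability logistic(α + β·copies + β_sex·sex)
with α = logit(0.01) so null prevalence is ~1% (keeps rejection sampling
efficient and matches a disease of ~1% worldwide frequency), rejection
sampling until quotas are met (attempt cap 2000 × quota + 100 000),
genotypes masked to missing at rate 0.002 (typical post-QC array
missingness). Everything is reproducible from the seed via spawned
per-cohort generators.

What the generator does **not** emulate: genotyping error beyond uniform
missingness, within-region recombination and rare haplotypes (the real
locus has >4 haplotypes at low frequency), population substructure within
cohorts, covariate effects on ascertainment, and imputation artefacts.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated model, not robustness to those real-data complications.

## Problem sizes used in tests

The test suite runs the full pipeline on 50 replicates at scale 0.25
(~6 300 samples each) for parameter recovery, 600 null replicates of
n = 400 for type-I calibration, 100 random ≤5-SNP fixtures against a dense
exhaustive-EM oracle, and exact-enumeration checks of the HWE test up to
n = 200. The acceptance script uses 12 scale-0.25 replicates. These sizes
give Monte-Carlo error comfortably inside the asserted tolerances (e.g.
the mean protective-OR estimate has SE ≈ 0.01 over 50 replicates against a
±0.05 band).

## Known limitations

- Haplotype-level EM assumes Hardy–Weinberg at the haplotype level;
  strong inbreeding or substructure within a cohort would bias frequencies.
- The Gabriel-CI block parameters are declared defaults, not inferred from
  any particular dataset; block boundaries are sensitive to them.
- The consensus core mode is a documented construction, not a published
  algorithm; strict mode is the defensible default.
- Exact logistic regression is not provided; separated fits are flagged,
  not resolved (no Firth correction).
- Only biallelic SNPs are supported (no indels, no multi-allelics, no
  dosage genotypes; binary PLINK BED is out of scope).
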