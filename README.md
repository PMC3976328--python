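# haplofine

Cross-population haplotype fine-mapping of case/control association
regions.

## The problem

A genome-wide association signal usually marks a block of linkage
disequilibrium (LD), not a variant: tens of kilobases where dozens of SNPs
are statistically interchangeable. `haplofine` implements the
multi-population haplotype strategy for shrinking such a region, built
around the celiac-disease *LPP* locus as its reference analysis: a 70 kb
intronic LD block on chromosome 3 genotyped in six case/control cohorts
(UK, Italy, Netherlands, Spain, Poland, India), where the strongest signal
(rs2030519, minor allele G) is protective with OR ≈ 0.75. Because
recombination histories differ between populations, the most-associated
haplotype block differs per cohort, and the *intersection* of those blocks
— the core haplotype — is much smaller than any single cohort's block.
Comparing the risk and protective alleles over the core then isolates the
SNPs that actually distinguish the two haplotypes, and regulatory
annotation ranks those for functional follow-up.

## What the package computes

For cohorts *c* with genotype dosage *g* (0/1/2 minor alleles) and
covariates (sex, country):

- **Per-SNP association** — logistic regression
  logit P(case) = α + β·g + γᵀx, Wald tests, OR = e^β with 95% CI; joint
  analysis pools all cohorts with population indicator covariates, and a
  stepwise conditional scan re-tests every SNP with the lead SNP's dosage
  as covariate. QC: pooled MAF and an exact Hardy–Weinberg test in
  controls.
- **Phasing and LD** — haplotype frequencies by EM over unphased
  genotypes (deterministic product-frequency initialisation, frequency
  floor with pruning), two-locus r²/D′ by the same EM, and Gabriel-style
  D′-confidence-interval haplotype blocks.
- **Haplotype association** — each common haplotype tested one-vs-rest by
  logistic regression on its expected copy count (posterior dosage).
- **Fine-mapping** — Bonferroni gate on the anchor-SNP p-value per cohort
  (α/k, here 0.05/6 = 0.008); strict core = [max of block starts, min of
  block ends] over the gated cohorts' top blocks; a SNP is
  *differentiating* iff the protective haplotype carries its minor allele
  and the risk haplotype its major allele; the refined region is the span
  of differentiating SNPs.
- **Annotation** — LD-proxy expansion (r² ≥ 0.9), overlap with BED
  feature tracks, and PWM motif-disruption scoring (best log₂
  likelihood-ratio placement over both strands, alt minus ref).

A bundled generator (`haplofine.simulate`) draws synthetic versions of the
six cohorts from a four-haplotype pool with the published per-cohort
control frequencies and a protective causal haplotype (OR 0.75) active in
the four European cohorts, so every stage is testable against known truth.

## Worked example

Simulate a 10%-scale six-cohort study and fine-map it:

```sh
haplofine simulate --scale 0.1 --seed 1 --out-dir sim
# write config.yaml listing sim/<pop>.vcf + sim/<pop>.pheno.tsv per cohort
haplofine run --config config.yaml --out-dir out
```

The run prints (abridged):

```json
{
  "bonferroni_threshold": 0.008,
  "gated_populations": ["Netherlands", "UK"],
  "conditional_min_p": 0.1775547828839087,
  "protective_haplotype": {"haplotype": "GATCTGGCGCAT", "or": 0.7556, "p": 3.9e-05},
  "risk_haplotype": {"haplotype": "CTCTAAATATTC", "or": 1.189, "p": 0.0095},
  "refined_interval": {
    "start_bp": 188117070, "end_bp": 188119901, "span_kb": 2.8,
    "n_differentiating_snps": 7,
    "differentiating_snps": ["rs6790260", "rs6444285", "rs4686483",
      "rs4686484", "rs6778720", "rs2030520", "rs2030519"]
  },
  "status": "ok"
}
```

Reading this: only the two cohorts whose anchor-SNP p-value cleared
0.05/6 enter the core intersection at this small scale; conditioning on
the lead SNP leaves no residual signal (min p = 0.18), consistent with a
single causal haplotype; the protective haplotype's OR estimate (0.76)
brackets the generating value 0.75; and seven SNPs separate the
protective from the risk haplotype, spanning a 2.8 kb refined region
(chr3:188117070–188119901) that contains the causal tag SNP rs2030519.
`out/` holds per-stage TSV tables, `summary.json` (the machine-readable
twin of the printed numbers) and a −log10(p) SVG track.

Every stage is also runnable standalone (`haplofine assoc`, `meta`,
`condition`, `phase`, `hapassoc`, `finemap`, `annotate`); see
`haplofine --help`.

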