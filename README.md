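# polyfacet

Polygenic-score construction and deep-phenotyping evaluation: genotype QC,
clumping+thresholding scores, and incremental-R² association batteries.

## The problem

Large GWAS of cognition measure their phenotype crudely ("light
phenotyping") but in hundreds of thousands of people; a deep-phenotyping
study measures many fine-grained cognitive abilities in a few hundred
participants and asks how much of each a polygenic score (PGS) from the big
studies can predict. The analysis chain is always the same — array-style
genotype QC, score construction from discovery summary statistics under
p-value-threshold (PT) schemes, covariate-adjusted regression per measure,
multiplicity control — and it is exactly the part that goes unreproduced
when the cohort genotypes cannot be shared. polyfacet implements that chain
as a tested library, together with a synthetic-data generator with known
ground truth so every stage can be validated end to end.

It is aimed at people who run or review PGS analyses on modest cohorts:
each stage is callable on its own (and on real PLINK filesets), and the
generator doubles as a power/robustness sandbox.

## What it computes

A polygenic score is a weighted allele sum
`PGS_i = Σ_j β̂_j · d_ij`, with `β̂_j` the discovery-GWAS effect of the
effect allele and `d_ij` the allele dosage, over SNPs with discovery
`p ≤ PT`. Three PT schemes are built per score label: fixed `PT = 0.05`,
the empirical best fit over the grid `{5·10⁻⁸ + k·5·10⁻⁵} ∩ (0, 0.5]`
(10,000 thresholds, one cumulative pass), and all SNPs (`PT = 1.00`).
Predictive power per cognitive measure is the incremental R²,

```
ΔR² = R²(sex + age + PC1..4 + PGS) − R²(sex + age + PC1..4),
```

with the two-sided p-value of the PGS coefficient, Benjamini–Hochberg
correction across the full battery (3 scores × 9 measures × 3 schemes = 81
tests), sex-stratified re-evaluation (best-fit PT frozen at the full-sample
choice), a bootstrap between-sex comparison of ΔR², and a-priori sample-size
planning via the noncentral-F power curve.

Upstream QC mirrors PLINK conventions: MAF < 0.01, Hardy–Weinberg exact
p < 10⁻⁶ (Levene–Haldane), missingness > 0.02 (variants and samples),
heterozygosity |F| > 0.2, pi-hat > 0.2 relatedness exclusion on an LD-pruned
(r² = 0.1) high-quality subset, and |6 SD| outlier removal on the first 20
stratification PCs.

## Worked example

`python examples/full_pipeline.py` simulates a 600-sample × 2000-variant
cohort (5% of each phenotype's variance from the latent score), runs QC,
builds IQ/CP/EA-analog scores and prints the 81-row battery. Excerpt of the
output:

```
scheme: fixed
  IQ-PGS
    general_intelligence     incremental R2 =  3.36%  (PT=0.05, n_snps=338) ***
    verbal_intelligence      incremental R2 =  3.91%  (PT=0.05, n_snps=338) ***
    figural_intelligence     incremental R2 =  1.13%  (PT=0.05, n_snps=338) *
    memory                   incremental R2 =  5.24%  (PT=0.05, n_snps=338) ***
```

Each line: the share of that measure's variance explained by the score on
top of sex, age and four ancestry PCs, the threshold and SNP count that
built the score, and stars at BH-adjusted p ≤ 0.05/0.01/0.001. Values
scatter around the generating 5% because a finite discovery GWAS attenuates
the realized score.

Other entry points, one capability each:

| script | shows |
| --- | --- |
| `examples/simulate_cohort.py` | generator ground truth and variance bookkeeping |
| `examples/qc_walkthrough.py` | each injected QC failure caught by its intended filter |
| `examples/score_and_evaluate.py` | battery + best-fit PT per measure |
| `examples/sex_stratified.py` | t tests, per-sex ΔR², bootstrap comparison |
| `examples/power_analysis.py` | minimal N for f² = 0.08 at 90% power |

The same stages are available as a CLI
(`polyfacet simulate|qc|score|evaluate|run|power`), reading and writing
PLINK 1 filesets, tab-separated summary statistics (SNP/CHR/BP/A1/A2/BETA/
SE/P/N) and FID/IID phenotype tables.

```bash
polyfacet power --f2 0.08 --alpha 0.05 --power 0.90 --u 7
# N = 236 (achieved power 0.9005 at f2=0.08, alpha=0.05, u=7)
```

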