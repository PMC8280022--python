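# Methods

polyfacet implements the analysis chain of a deep-phenotyping polygenic-score
(PGS) study: a modestly sized, richly phenotyped target cohort is scored with
weights from large external discovery GWAS, and each of nine cognitive
measures is regressed on each score under three p-value-threshold schemes.
Because such studies' raw genotypes are rarely shareable, the package ships a
first-class synthetic-data generator with known ground truth; every downstream
stage is exercised against it.

## Synthetic cohort generator (`simdata`)

**Genotypes.** Each variant has a generating allele frequency drawn uniformly
from `maf_range` (default 0.05–0.5). Per haplotype, a standard-normal AR(1)
latent process with parameter `ld_decay` (default 0.6) runs within each block
of `ld_block_size` variants (default 50); an allele is present when the latent
value is below the frequency quantile. Two independent haplotypes per
individual guarantee exact Hardy–Weinberg proportions; LD exists only within
blocks, and blocks never span chromosomes (10 blocks per chromosome, 1 kb
marker spacing). At `ld_decay = 0.6` adjacent variants show genotype r² around
0.12 — enough that pruning at r² = 0.1 and clumping both do real work.
Missing calls are missing-at-random but concentrated: only ~20% of variants
carry any missingness (at five times the overall rate, default 0.002), so a
zero-missingness high-quality subset exists, as on real arrays where
missingness clusters by assay.

**Discovery summary statistics.** A fraction `prop_causal` (default 0.2) of
variants receives standardized effects scaled so the latent score explains
the target phenotype share on the standardized discovery trait. Reported
per-allele effects are truth plus N(0, se²) noise with
se = (N_discovery · 2pq)^{-1/2}, the standard approximation for a
standardized phenotype; p-values are two-sided Wald. The three score labels
(IQ / CP / EA analogs, discovery N 269,867 / 257,828 / 766,345) share one
genetic architecture and differ only in sampling noise — a deliberate
simplification of three highly genetically correlated discovery traits.
`discovery_n = inf` is the noise-free limit (reported = true effects).

**Phenotypes.** Nine unit-variance measures, all oriented higher-is-better
(the processing-speed measure is sign-flipped at generation so no downstream
inversion exists). Each is
`√v_g·g + d·(male−½) + b·age_std + √v_c·shared + √v_e·noise` with
v_g = `score_r2`, a shared factor sized to approach `battery_correlation`
(default 0.3) and an independent remainder; the generator refuses
configurations whose variance budget exceeds one. Age is uniform on 18–75
(covariate only). Default sex effects are standardized mean differences
calibrated so t statistics at n≈557 match the magnitudes typical of such
batteries (males higher on knowledge/numerical/general, females higher on
memory, near-zero elsewhere). The per-phenotype variance decomposition
(genetic / covariate / noise, summing to one) is part of the ground truth and
is verified empirically at n = 10,000 within ±0.02.

**Injected QC failures.** Duplicates (genotype-identical appended samples),
Mendelian parent–offspring trios (child alleles transmitted Bernoulli(d/2)),
high-missingness samples (10% missing calls), heterozygote-free HWE
violations, rare columns (MAF 0.005), and an ancestry-shifted subgroup.
Ancestry outliers are resampled at frequencies interpolated toward the
mirror 1−p (default: full mirror). The mirror is chosen deliberately: it
preserves each sample's expected heterozygosity (so the |F| filter stays
silent), leaves every pairwise IBS expectation unchanged (all moment terms
are symmetric in p↔q, so pi-hat stays null), and maximizes the principal-
component signal — the failure lands exactly on the filter meant to catch it.
A milder random per-variant offset fails on all three counts at desk-scale
marker numbers.

## Quality control (`genoqc`)

Filters run in fixed order with strict, PLINK-convention inequalities:
variants with MAF < 0.01, HWE exact p < 1e-6 or missingness > 0.02; then
samples with missingness > 0.02 or |F| > 0.2 (F = 1 − observed/expected
heterozygosity at cohort frequencies — the "heterozygosity rate" bound read
as the inbreeding coefficient, since an absolute bound on a raw het fraction
would be vacuous). Sex-mismatch checking is a logged no-op: the synthetic
data are autosomal. Exact boundary values are retained; missing rates are
computed as integer-count ratios so boundaries like 1/50 = 0.02 compare
exactly.

The HWE test is the exact conditional (Levene–Haldane) test: with allele
counts fixed, the p-value sums the probabilities of all heterozygote counts
no more probable than the observed one. The pmf is built by the stable
two-sided recurrence from the modal count (vectorized); the test suite checks
it against an independent log-gamma closed-form enumeration over the
exhaustive grid of totals ≤ 200 at 1e-12 relative.

Relatedness and stratification run on a high-quality subset (HWE p > 0.02,
MAF > 0.2, zero missingness) pruned by greedy sliding-window LD pruning
(window 50, step 5, r² > 0.1 removes the lower-MAF member, ties to the later
position). Pi-hat is plain method-of-moments IBD from observed vs expected
IBS counts at cohort frequencies, truncated to the probability simplex,
without finite-sample bias-correction factors; its sampling sd is ≈0.7/√m,
so the package's QC examples simulate enough variants that ≥ ~2000 markers
survive pruning, keeping the noise floor well below the pi-hat > 0.2
exclusion threshold. (With ~1000 markers a few of 10⁵ unrelated pairs cross
0.2 — an estimator-precision fact worth knowing before trusting relatedness
calls on small marker panels.) One member of each offending pair is removed
by a seeded uniform draw.

Stratification PCs come from the SVD of the centered, unit-variance,
mean-imputed genotype matrix (truncated to the leading components when that
is cheaper). Outliers beyond 6 SD on any of the first 20 PCs are removed in
a single pass — no iterative recomputation — but the PCs returned for use as
regression covariates are recomputed on the retained samples. Re-running QC
on its own output can therefore remove new PCA outliers (documented
non-idempotence); all other filters are idempotent.

## Scoring (`scoring`)

Harmonization matches by variant id; effect alleles align directly, by swap
(beta negated) or by strand complement; strand-ambiguous A/T and C/G variants
are removed unconditionally (stricter than frequency-based rescue, but
unambiguous); chromosome/position disagreements are logged, not fatal.
Clumping is ON by default with PRSice-2 defaults (r² = 0.1, 250 kb, p1 = 1):
greedy p-ascending index selection, ties by position. Scores are raw weighted
dosage sums — incremental R² is invariant to linear rescaling — with missing
dosages imputed at twice the effect-allele frequency, keeping the score
expectation unbiased.

The threshold sweep covers {5e-8 + k·5e-5} ∩ (0, 0.5] — exactly 10,000
thresholds. Variants are p-sorted once and contributions cumulated, so the
whole sweep is one cumulative-sum pass; thresholds sharing an inclusion count
share one stored score column. Equality with direct per-threshold
recomputation is asserted to 1e-10 relative.

## Evaluation (`evalstats`)

Incremental R² = R²(covariates + score) − R²(covariates), both OLS fits on
identical complete-case rows; its p-value is the two-sided test of the score
coefficient (the 1-df F test of the increase). The battery covariates are
sex, age and the first four stratification PCs. The sweep evaluation uses the
partial-correlation identity incR² = (1 − R²_base)·r²_resid, vectorized
across score columns and verified against the statsmodels fits to 1e-10.
Best-fit selection takes the grid argmax, ties to the smallest PT — and is,
by construction, optimistically biased; the acceptance suite demonstrates the
bias on null data, which is exactly why the fixed-PT and all-SNP schemes are
reported alongside.

The 3 labels × 9 phenotypes × 3 schemes = 81 raw p-values are corrected as a
single Benjamini–Hochberg family (step-up; adjusted p by the monotone
cumulative-minimum transform). Sex-stratified analyses (covariates age +
PCs; best-fit PT frozen at the full-sample choice per phenotype) form their
own family, as does the set of between-sex comparisons. The between-sex test
of incremental R² — a quantity whose sampling law is awkward — is a seeded
within-group bootstrap (default B = 2000) with a two-sided percentile
p-value and plus-one smoothing, chosen because no standard named test
exists for an R² difference between independent samples.

Sample-size planning inverts the power of the F test for R² ≠ 0 in multiple
regression: noncentral F with numerator df u, denominator df N − u − 1,
noncentrality f²·N. With u = 7 (score + sex + age + four PCs), f² = 0.08,
α = 0.05, power 0.90 the minimal N is 236; u is a parameter, because power
programs differ in which test variant they expose, and u = 7 is the variant
consistent with the published requirement.

## Pipeline (`pipeline`, CLI)

`run_pipeline` drives simulate → qc → score → evaluate from one RunConfig;
per-stage seeds derive from SHA-256 of (master seed, stage name), all below
2³¹. Outputs are tab-separated with a comment header carrying the config
hash (output directory excluded from the hash so relocated runs stay
comparable); `summary.txt` prints incremental R² in percent with
significance stars at adjusted p ≤ 0.05/0.01/0.001. The `polyfacet` CLI is a
thin click layer (`simulate|qc|score|evaluate|run|power`), exit codes
0/1/2 for success/user error/internal error.

## Test and acceptance problem sizes

Chosen so the whole suite runs comfortably on one CPU:

- parameter recovery / null calibration: 100 seeds at 2000 samples × 5000
  variants, true-score regressions; null phenotypes share the battery with
  `battery_correlation = 0` so their p-values are independent for the KS
  uniformity check;
- selection optimism: 200 null replicates at 300 × 400 with the full
  10,000-point sweep;
- oracle equivalence: exhaustive HWE grid (totals ≤ 200, every admissible
  heterozygote count, hom-class symmetry spot-checked), 50 brute-force score
  instances, 200 BH vectors, nested-loop clumping reference;
- QC attribution: one failure of each class at 500 × 6000 (marker count per
  the pi-hat precision note above);
- the bootstrap type-I check runs at 250/group, 60 replicates, B = 199 —
  a coarse bound (rejection rate ≤ 0.12), not a calibration claim.

## What the generator does not emulate

Realistic recombination maps and long-range LD, allele-frequency spectra
(no rare-variant tail beyond injected failures), genotyping batch effects,
imputation uncertainty, sex chromosomes (hence the no-op sex check),
trans-ancestry LD differences, instrument-specific score scales and
ceilings, and selection/attrition in cohort recruitment. Passing tests
therefore show the machinery is correct under a clean polygenic model —
not that effect sizes from any real cohort transfer.

## Known limitations

- Pi-hat method-of-moments precision at small marker counts (see above);
  KING-robust kinship is out of scope.
- The latent-Gaussian LD model has no haplotype-block boundaries within a
  block and constant decay; clumping behaves realistically but index-variant
  choice on real data is messier.
- PCA outlier removal is single-pass; iterated removal can flag secondary
  outliers once dominant ones are gone.
- The bootstrap comparison of incremental R² is approximate in small
  subgroups; B ≥ 1000 and groups ≥ ~100 are sensible floors.
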