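"""Synthetic cohort generator: genotypes, discovery summary statistics,
a nine-measure cognitive battery, and injectable QC failures.

The generator emulates a deep-phenotyping PGS study design: a target
sample of unrelated adults genotyped on a SNP array, discovery GWAS
effect estimates from a much larger external cohort, and a battery of
nine correlated cognitive measures of which a stated share of variance
is attributable to the latent polygenic score.

Genotypes follow a latent-Gaussian block-LD model: per haplotype, a
standard-normal AR(1) process with parameter ``ld_decay`` runs within
each block (blocks never span chromosomes) and an allele is present
whenever the latent value falls below the quantile of that variant's
generating frequency.  Hardy-Weinberg proportions hold exactly because
the two haplotypes are independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    ConfigError,
    FailureSpec,
    PHENOTYPES,
    SimulationConfig,
)
from .datatypes import GenotypeDataset, GroundTruth, SummaryStatistics

# Ordered, non-palindromic allele pairs (strand-ambiguous A/T and C/G
# pairs are exercised in dedicated harmonization tests instead).
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

# Discovery sample sizes of the three score labels (intelligence,
# cognitive performance, educational attainment).
DEFAULT_DISCOVERY_NS = {"IQ": 269_867, "CP": 257_828, "EA": 766_345}

# Fraction of variants that carry any missing calls; the overall missing
# rate stays at config.missing_rate.
_SLOPPY_FRACTION = 0.2

_AGE_LO, _AGE_HI = 18.0, 75.0
_AGE_SD = (_AGE_HI - _AGE_LO) / np.sqrt(12.0)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw a sample x variant dosage matrix with block LD.

    Variant metadata carries chromosome, 1-based position and two allele
    labels; sample metadata carries balanced sex codes (1=male, 2=female).
    Identical config (including seed) gives bit-identical output.
    """
    rng = _rng(config.seed, 1)
    n, m = config.n_samples, config.n_variants

    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(freqs)

    block = np.arange(m) // config.ld_block_size

    rho = config.ld_decay
    c = np.sqrt(1.0 - rho**2)
    eps = rng.standard_normal((2 * n, m), dtype=np.float32)
    if rho == 0:
        z = eps
    else:
        # stationary AR(1) per block: z_j = rho*z_{j-1} + c*eps_j with
        # z_0 = eps_0; blocks are independent, so filter blockwise
        from scipy.signal import lfilter

        z = np.empty_like(eps)
        for b in range(block[-1] + 1):
            cols = np.flatnonzero(block == b)
            e = eps[:, cols] * np.float32(c)
            e[:, 0] = eps[:, cols[0]]
            z[:, cols] = lfilter([1.0], [1.0, -rho], e, axis=1)

    alleles = z < thresholds.astype(np.float32)
    dosages = alleles[:n].astype(float)
    dosages += alleles[n:]

    if config.missing_rate > 0:
        # Array missingness clusters by assay: only a fraction of variants
        # miss calls at all, at an elevated per-call rate, so that the
        # remainder stay at exactly zero missingness (as on real chips).
        sloppy = rng.random(m) < _SLOPPY_FRACTION
        per_call = min(config.missing_rate / _SLOPPY_FRACTION, 1.0)
        miss = (rng.random((n, m)) < per_call) & sloppy
        dosages[miss] = np.nan

    chrom = block // config.blocks_per_chrom + 1
    pos = np.empty(m, dtype=int)
    for ch in np.unique(chrom):
        idx = np.flatnonzero(chrom == ch)
        pos[idx] = (np.arange(len(idx)) + 1) * config.bp_spacing
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "a2": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )

    sex = np.ones(n, dtype=int)
    sex[n // 2:] = 2
    rng.shuffle(sex)
    samples = pd.DataFrame(
        {
            "fid": [f"F{i + 1}" for i in range(n)],
            "iid": [f"S{i + 1}" for i in range(n)],
            "sex": sex,
        }
    )
    return GenotypeDataset(dosages, variants, samples)


def _standardized_genotypes(dataset: GenotypeDataset, freqs: np.ndarray) -> np.ndarray:
    """Mean-imputed, (2pq)^-1/2-scaled dosage matrix."""
    d = dataset.dosages.copy()
    fill = 2.0 * freqs
    nan = np.isnan(d)
    d[nan] = np.broadcast_to(fill, d.shape)[nan]
    denom = np.sqrt(np.maximum(2.0 * freqs * (1.0 - freqs), 1e-12))
    return (d - 2.0 * freqs) / denom


def _draw_architecture(
    dataset: GenotypeDataset, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Causal indices, standardized true betas, and the latent score."""
    m = dataset.n_variants
    n_causal = max(1, int(round(config.prop_causal * m)))
    causal = np.sort(rng.choice(m, size=n_causal, replace=False))

    target = float(np.max(config.score_r2_vector))
    beta_std = np.zeros(m)
    if target > 0:
        raw = rng.standard_normal(n_causal)
        raw *= np.sqrt(target / np.sum(raw**2))
        beta_std[causal] = raw

    freqs = dataset.allele_freq()
    freqs = np.where(np.isnan(freqs), 0.5, freqs)
    g_std = _standardized_genotypes(dataset, freqs)
    score = g_std @ beta_std
    sd = score.std()
    if sd > 0:
        score = (score - score.mean()) / sd
    return causal, beta_std, score


def _noisy_sumstats(
    dataset: GenotypeDataset,
    beta_std: np.ndarray,
    discovery_n: float,
    rng: np.random.Generator,
) -> SummaryStatistics:
    """True per-allele effects plus discovery sampling noise, with SE and
    two-sided Wald p consistent with ``discovery_n``."""
    freqs = dataset.allele_freq()
    freqs = np.where(np.isnan(freqs), 0.5, freqs)
    het = np.maximum(2.0 * freqs * (1.0 - freqs), 1e-12)
    beta_true = beta_std / np.sqrt(het)

    if np.isinf(discovery_n):
        se = np.zeros_like(beta_true)
        beta_hat = beta_true.copy()
        p = np.where(beta_hat != 0, np.nextafter(0, 1), 1.0)
    else:
        se = 1.0 / np.sqrt(discovery_n * het)
        beta_hat = beta_true + rng.standard_normal(len(beta_true)) * se
        z = beta_hat / se
        p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))

    table = pd.DataFrame(
        {
            "id": dataset.variants["id"],
            "chrom": dataset.variants["chrom"],
            "pos": dataset.variants["pos"],
            "effect_allele": dataset.variants["a1"],
            "other_allele": dataset.variants["a2"],
            "beta": beta_hat,
            "se": se,
            "p": p,
            "n": int(discovery_n) if np.isfinite(discovery_n) else -1,
        }
    )
    return SummaryStatistics(table)


def simulate_summary_stats(
    dataset: GenotypeDataset, config: SimulationConfig
) -> tuple[SummaryStatistics, GroundTruth]:
    """Simulate one discovery GWAS over the dataset's variants.

    True standardized effects are scaled so the latent score explains the
    configured variance share on the standardized discovery trait; the
    reported effect is the truth plus N(0, se^2) noise with
    se = (discovery_n * 2pq)^-1/2.
    """
    rng = _rng(config.seed, 2)
    causal, beta_std, score = _draw_architecture(dataset, config, rng)
    sumstats = _noisy_sumstats(dataset, beta_std, config.discovery_n, _rng(config.seed, 3))
    ids = dataset.variants["id"]
    truth = GroundTruth(
        causal_ids=ids.iloc[causal].tolist(),
        true_betas=pd.Series(beta_std, index=ids.to_numpy(), name="beta_std"),
        true_score=score,
        variance_shares=pd.DataFrame(),
    )
    return sumstats, truth


def simulate_phenotypes(
    true_score: np.ndarray,
    samples: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the nine-measure battery plus age for each sample.

    Each phenotype k is built on the unit-variance scale as

        y_k = sqrt(v_g) * g  +  d_k * (male - 1/2)  +  b_k * age_std
              + sqrt(v_c) * shared  +  sqrt(v_e) * noise

    with v_g = score_r2[k], v_c chosen so phenotype pairs correlate near
    ``battery_correlation``, and v_e filling the remainder.  All measures
    are oriented higher-is-better (processing speed included).  Returns
    the sample table and the per-phenotype variance decomposition
    (genetic / covariate / noise shares, summing to one).
    """
    n = len(samples)
    if len(true_score) != n:
        raise ValueError(
            f"true_score has length {len(true_score)} but samples table has {n} rows"
        )
    rng = _rng(config.seed, 4)
    age = rng.uniform(_AGE_LO, _AGE_HI, size=n)
    age_std = (age - (_AGE_LO + _AGE_HI) / 2.0) / _AGE_SD
    x_sex = np.where(samples["sex"].to_numpy() == 1, 0.5, -0.5)
    shared = rng.standard_normal(n)

    v_g = config.score_r2_vector
    d = config.sex_effect_vector
    b_a = config.age_effect_vector
    cov_share = d**2 / 4.0 + b_a**2
    v_c = np.maximum(config.battery_correlation - v_g, 0.0)
    v_e = 1.0 - v_g - cov_share - v_c
    bad = np.flatnonzero(v_e < 0)
    if bad.size:
        raise ConfigError(
            f"variance budget exceeded for phenotype(s) {[PHENOTYPES[i] for i in bad]}: "
            "genetic + covariate + shared shares must stay below 1"
        )

    out = pd.DataFrame(
        {"fid": samples["fid"].to_numpy(), "iid": samples["iid"].to_numpy(),
         "sex": samples["sex"].to_numpy(), "age": age}
    )
    for k, name in enumerate(PHENOTYPES):
        noise = rng.standard_normal(n)
        out[name] = (
            np.sqrt(v_g[k]) * true_score
            + d[k] * x_sex
            + b_a[k] * age_std
            + np.sqrt(v_c[k]) * shared
            + np.sqrt(v_e[k]) * noise
        )

    shares = pd.DataFrame(
        {
            "genetic": v_g,
            "covariate": cov_share,
            "noise": v_c + v_e,
        },
        index=list(PHENOTYPES),
    )
    return out, shares


@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, with known ground truth."""

    dataset: GenotypeDataset
    sumstats: dict[str, SummaryStatistics]
    phenotypes: pd.DataFrame
    truth: GroundTruth


def simulate_study(
    config: SimulationConfig,
    discovery_ns: dict[str, float] | None = None,
) -> SimulatedStudy:
    """Generate the full study: one genetic architecture shared by all
    discovery traits, one summary-statistic set per score label (noise
    drawn at that label's discovery N), and the phenotype battery."""
    if discovery_ns is None:
        discovery_ns = dict(DEFAULT_DISCOVERY_NS)
    dataset = simulate_genotypes(config)
    rng = _rng(config.seed, 2)
    causal, beta_std, score = _draw_architecture(dataset, config, rng)
    sumstats = {
        label: _noisy_sumstats(dataset, beta_std, n_disc, _rng(config.seed, 20 + i))
        for i, (label, n_disc) in enumerate(sorted(discovery_ns.items()))
    }
    phenotypes, shares = simulate_phenotypes(score, dataset.samples, config)
    ids = dataset.variants["id"]
    truth = GroundTruth(
        causal_ids=ids.iloc[causal].tolist(),
        true_betas=pd.Series(beta_std, index=ids.to_numpy(), name="beta_std"),
        true_score=score,
        variance_shares=shares,
    )
    return SimulatedStudy(dataset, sumstats, phenotypes, truth)


def inject_qc_failures(
    dataset: GenotypeDataset, spec: FailureSpec
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Plant known QC positives and return (dataset, manifest).

    Sample-level failures: appended duplicate copies, appended Mendelian
    offspring of two existing parents, high-missingness samples, and an
    ancestry-shifted subgroup resampled at mirrored allele frequencies
    (heterozygosity-preserving, so it targets the PCA filter
    specifically).  Variant-level failures: heterozygote-free HWE
    violations and rare (MAF < 0.01) columns.  The manifest lists every
    injected id with its failure class.
    """
    n, m = dataset.n_samples, dataset.n_variants
    need_samples = (
        spec.n_duplicates
        + 2 * spec.n_parent_offspring
        + spec.n_high_missing_samples
        + spec.n_ancestry_outliers
    )
    if need_samples > n:
        raise ConfigError(
            f"requested failures need {need_samples} distinct source samples, only {n} available"
        )
    if spec.n_hwe_violations + spec.n_rare_variants > m:
        raise ConfigError("requested variant failures exceed the number of variants")
    if spec.total == 0:
        return dataset.copy(), pd.DataFrame(columns=["kind", "class", "id", "partner"])

    rng = _rng(spec.seed, 9)
    out = dataset.copy()
    freqs = np.where(np.isnan(out.allele_freq()), 0.5, out.allele_freq())
    manifest: list[dict] = []

    picks = rng.permutation(n)[:need_samples]
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        sel = picks[cursor:cursor + k]
        cursor += k
        return sel

    new_rows: list[np.ndarray] = []
    new_meta: list[dict] = []

    for i, src in enumerate(take(spec.n_duplicates)):
        iid = out.samples.at[src, "iid"]
        dup_iid = f"{iid}_dup"
        new_rows.append(dataset.dosages[src].copy())
        new_meta.append({"fid": "DUP", "iid": dup_iid, "sex": out.samples.at[src, "sex"]})
        manifest.append({"kind": "duplicate", "class": "sample", "id": dup_iid, "partner": iid})

    for i in range(spec.n_parent_offspring):
        p1, p2 = take(2)
        child = np.empty(m)
        for parent_idx, half in ((p1, 0), (p2, 1)):
            d = dataset.dosages[parent_idx]
            prob = np.where(np.isnan(d), freqs, d / 2.0)
            t = rng.random(m) < prob
            child = t.astype(float) if half == 0 else child + t
        child_iid = f"child{i + 1}"
        new_rows.append(child)
        new_meta.append({"fid": "TRIO", "iid": child_iid, "sex": int(rng.integers(1, 3))})
        manifest.append(
            {
                "kind": "parent_offspring",
                "class": "sample",
                "id": child_iid,
                "partner": f"{out.samples.at[p1, 'iid']};{out.samples.at[p2, 'iid']}",
            }
        )

    if new_rows:
        out = GenotypeDataset(
            np.vstack([out.dosages] + [r[None, :] for r in new_rows]),
            out.variants,
            pd.concat([out.samples, pd.DataFrame(new_meta)], ignore_index=True),
        )

    for src in take(spec.n_high_missing_samples):
        mask = rng.random(m) < spec.high_missing_rate
        out.dosages[src, mask] = np.nan
        manifest.append(
            {"kind": "high_missing", "class": "sample",
             "id": out.samples.at[src, "iid"], "partner": ""}
        )

    shifted = take(spec.n_ancestry_outliers)
    if len(shifted):
        # resample the subgroup at frequencies interpolated toward the
        # mirror 1-p: a maximally divergent synthetic population whose
        # expected heterozygosity matches the cohort (full mirror), so
        # only the stratification PCA - not the |F| filter - catches it
        w = spec.ancestry_shift
        p_shift = (1.0 - w) * freqs + w * (1.0 - freqs)
        out.dosages[shifted] = rng.binomial(2, p_shift, size=(len(shifted), m)).astype(float)
        for src in shifted:
            manifest.append(
                {"kind": "ancestry", "class": "sample",
                 "id": out.samples.at[src, "iid"], "partner": ""}
            )

    n_now = out.n_samples
    var_picks = rng.permutation(m)[: spec.n_hwe_violations + spec.n_rare_variants]
    for j in var_picks[: spec.n_hwe_violations]:
        col = np.where(np.arange(n_now) % 2 == 0, 0.0, 2.0)
        rng.shuffle(col)
        out.dosages[:, j] = col
        manifest.append(
            {"kind": "hwe_violation", "class": "variant",
             "id": out.variants.at[j, "id"], "partner": ""}
        )
    for j in var_picks[spec.n_hwe_violations:]:
        col = np.zeros(n_now)
        k_het = max(1, int(round(2 * n_now * spec.rare_maf)))
        col[rng.permutation(n_now)[:k_het]] = 1.0
        out.dosages[:, j] = col
        manifest.append(
            {"kind": "rare_variant", "class": "variant",
             "id": out.variants.at[j, "id"], "partner": ""}
        )

    return out, pd.DataFrame(manifest, columns=["kind", "class", "id", "partner"])
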