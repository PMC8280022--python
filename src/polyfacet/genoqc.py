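"""Genotype quality control: variant and sample filters, relatedness,
and population-stratification PCA.

The stack mirrors standard array QC run with PLINK-style strict
inequalities: variants fail on MAF < 0.01, Hardy-Weinberg exact p <
1e-6, or missingness > 0.02; samples fail on missingness > 0.02 or
|inbreeding F| > 0.2; cryptic relatives (pi-hat > 0.2 on an LD-pruned
high-quality variant subset) are excluded at random; samples beyond
|6 SD| on any of the first 20 principal components are dropped as
ancestry outliers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import ConfigError, QCThresholds
from .datatypes import GenotypeDataset, QCReport, QCStep


# ---------------------------------------------------------------------------
# per-variant and per-sample statistics

def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_hom_a1 = np.nansum(dosages == 2.0, axis=0).astype(int)
    n_het = np.nansum(dosages == 1.0, axis=0).astype(int)
    n_hom_a2 = np.nansum(dosages == 0.0, axis=0).astype(int)
    return n_hom_a1, n_het, n_hom_a2


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided Hardy-Weinberg exact p-value (Levene-Haldane).

    With the allele counts fixed, heterozygote counts follow the exact
    conditional distribution; the p-value sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.  The pmf is built by the stable two-sided recurrence
    from the modal count.
    """
    for v in (n_hom1, n_het, n_hom2):
        if v < 0 or v != int(v):
            raise ValueError(f"genotype counts must be non-negative integers, got {v!r}")
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("all genotype counts are zero")

    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0

    # modal heterozygote count, parity-matched to the rare-allele count
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1 if mid < rare else -1

    # hets below mid: P(h-2) = P(h) * h(h-1) / (4 (homr(h)+1)(homc(h)+1))
    hets_down = np.arange(mid, 1, -2)
    homr_down = (rare - hets_down) // 2
    homc_down = n - hets_down - homr_down
    ratios_down = (
        hets_down * (hets_down - 1.0)
        / (4.0 * (homr_down + 1.0) * (homc_down + 1.0))
    )
    # hets above mid: P(h+2) = P(h) * 4 homr(h) homc(h) / ((h+1)(h+2))
    hets_up = np.arange(mid, rare - 1, 2)
    homr_up = (rare - hets_up) // 2
    homc_up = n - hets_up - homr_up
    ratios_up = (
        4.0 * homr_up * homc_up
        / ((hets_up + 1.0) * (hets_up + 2.0))
    )

    probs_down = np.cumprod(ratios_down) if len(ratios_down) else np.empty(0)
    probs_up = np.cumprod(ratios_up) if len(ratios_up) else np.empty(0)
    hets = np.concatenate((hets_down[::-1] - 2, [mid], hets_up + 2))
    probs = np.concatenate((probs_down[::-1], [1.0], probs_up))
    probs /= probs.sum()

    obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= obs * (1.0 + 1e-10)].sum()
    return float(min(p, 1.0))


def variant_stats(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-variant MAF, missing rate and HWE exact p.

    A variant with every call missing gets NaN MAF and hwe_p and
    missing_rate 1 (so the missingness filter removes it).
    """
    if dataset.n_variants == 0 or dataset.n_samples == 0:
        raise ValueError("empty dataset")
    d = dataset.dosages
    n_hom1, n_het, n_hom2 = _genotype_counts(d)
    n_obs = n_hom1 + n_het + n_hom2
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (2.0 * n_hom1 + n_het) / (2.0 * n_obs)
    maf = np.minimum(freq, 1.0 - freq)
    maf[n_obs == 0] = np.nan
    # integer-count ratio so exact boundaries (e.g. 1/50) compare cleanly
    missing_rate = (dataset.n_samples - n_obs) / dataset.n_samples
    hwe_p = np.full(dataset.n_variants, np.nan)
    for j in range(dataset.n_variants):
        if n_obs[j] > 0:
            hwe_p[j] = hwe_exact_test(n_hom1[j], n_het[j], n_hom2[j])
    return pd.DataFrame(
        {
            "id": dataset.variants["id"].to_numpy(),
            "maf": maf,
            "missing_rate": missing_rate,
            "hwe_p": hwe_p,
            "n_obs": n_obs,
        }
    )


def sample_stats(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-sample missing rate and inbreeding coefficient F.

    F = 1 - observed_het / expected_het with the expectation summed over
    the sample's non-missing variants at cohort allele frequencies.
    """
    d = dataset.dosages
    obs = ~np.isnan(d)
    missing_rate = (dataset.n_variants - obs.sum(axis=1)) / dataset.n_variants
    freq = dataset.allele_freq()
    exp_het_per_variant = 2.0 * freq * (1.0 - freq)
    exp_het_per_variant = np.where(np.isnan(exp_het_per_variant), 0.0, exp_het_per_variant)
    exp_het = obs @ exp_het_per_variant
    obs_het = np.nansum(d == 1.0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_f = 1.0 - obs_het / exp_het
    het_f[exp_het == 0] = 0.0
    return pd.DataFrame(
        {
            "iid": dataset.samples["iid"].to_numpy(),
            "missing_rate": missing_rate,
            "het_f": het_f,
        }
    )


# ---------------------------------------------------------------------------
# filters

def filter_variants(
    dataset: GenotypeDataset, thresholds: QCThresholds
) -> tuple[GenotypeDataset, list[QCStep]]:
    """Remove variants failing MAF, HWE or missingness (strict
    inequalities); each removal is attributed to the first failing
    filter in that order."""
    vs = variant_stats(dataset)
    maf_fail = (vs["maf"] < thresholds.maf_min) | vs["maf"].isna()
    hwe_fail = (vs["hwe_p"] < thresholds.hwe_p_min) & ~maf_fail
    miss_fail = (vs["missing_rate"] > thresholds.variant_miss_max) & ~maf_fail & ~hwe_fail

    steps: list[QCStep] = []
    out = dataset
    n_samples = dataset.n_samples
    for name, thr, fail in (
        ("variant_maf", f"maf<{thresholds.maf_min}", maf_fail),
        ("variant_hwe", f"hwe_p<{thresholds.hwe_p_min}", hwe_fail),
        ("variant_missing", f"miss>{thresholds.variant_miss_max}", miss_fail),
    ):
        removed = vs.loc[fail, "id"].tolist()
        out = out.drop_variants(removed)
        steps.append(QCStep(name, "variant", thr, removed, n_samples, out.n_variants))
    if out.n_variants == 0:
        raise ValueError("no variants remain after variant filters")
    return out, steps


def filter_samples(
    dataset: GenotypeDataset, thresholds: QCThresholds
) -> tuple[GenotypeDataset, list[QCStep]]:
    """Remove samples failing missingness or |F| (strict inequalities);
    the sex-mismatch check is logged as not evaluated (no sex
    chromosomes in scope)."""
    ss = sample_stats(dataset)
    miss_fail = ss["missing_rate"] > thresholds.sample_miss_max
    het_fail = (ss["het_f"].abs() > thresholds.het_abs_max) & ~miss_fail

    steps: list[QCStep] = []
    out = dataset
    for name, thr, fail in (
        ("sample_missing", f"miss>{thresholds.sample_miss_max}", miss_fail),
        ("sample_het", f"|F|>{thresholds.het_abs_max}", het_fail),
    ):
        removed = ss.loc[fail, "iid"].tolist()
        out = out.drop_samples(removed)
        steps.append(QCStep(name, "sample", thr, removed, out.n_samples, out.n_variants))
    steps.append(
        QCStep(
            "sex_mismatch", "info", "-", [], out.n_samples, out.n_variants,
            note="not evaluated (no sex chromosomes)",
        )
    )
    if out.n_samples == 0:
        raise ValueError("no samples remain after sample filters")
    return out, steps


def high_quality_subset(dataset: GenotypeDataset, thresholds: QCThresholds) -> list[str]:
    """Variant ids passing the high-quality criteria used for
    relatedness and PCA: HWE p > 0.02, MAF > 0.2, missingness = 0."""
    vs = variant_stats(dataset)
    keep = (
        (vs["hwe_p"] > thresholds.hq_hwe_p_min)
        & (vs["maf"] > thresholds.hq_maf_min)
        & (vs["missing_rate"] <= thresholds.hq_miss_max)
    )
    ids = vs.loc[keep, "id"].tolist()
    if not ids:
        raise ValueError(
            "high-quality subset is empty; simulate more variants or relax hq thresholds"
        )
    return ids


# ---------------------------------------------------------------------------
# LD pruning

def _imputed_standardized(d: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls, then center and unit-normalize columns."""
    col_mean = np.nanmean(d, axis=0)
    x = np.where(np.isnan(d), col_mean, d) - col_mean
    norms = np.sqrt((x**2).sum(axis=0))
    norms[norms == 0] = 1.0
    return x / norms


def ld_prune(
    dataset: GenotypeDataset,
    ids: list[str] | None = None,
    prune_r2: float = 0.1,
    window_size: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy windowed LD pruning.

    Within each sliding window (per chromosome), while any retained pair
    has genotype r^2 > ``prune_r2``, the pair's lower-MAF member is
    removed (ties by later position).  After completion no retained
    within-window pair exceeds the bound.
    """
    if window_size < 2:
        raise ConfigError(f"window_size must be >= 2, got {window_size}")
    if step < 1:
        raise ConfigError(f"step must be >= 1, got {step}")
    if ids is None:
        ids = dataset.variants["id"].tolist()
    idx = dataset.variant_indexer(ids)
    meta = dataset.variants.iloc[idx]
    order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
    idx = idx[order]
    meta = meta.iloc[order]

    x = _imputed_standardized(dataset.dosages[:, idx])
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dataset.dosages[:, idx], axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    pos = meta["pos"].to_numpy()
    chrom = meta["chrom"].to_numpy()

    keep = np.ones(len(idx), dtype=bool)
    for ch in pd.unique(chrom):
        where = np.flatnonzero(chrom == ch)
        start = 0
        while True:
            win = where[start:start + window_size]
            active = win[keep[win]]
            if len(active) >= 2:
                c = x[:, active].T @ x[:, active]
                r2 = c**2
                np.fill_diagonal(r2, 0.0)
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= prune_r2:
                        break
                    gi, gj = active[i], active[j]
                    # drop the lower-MAF member; ties by later position
                    if (maf[gi], -pos[gi]) <= (maf[gj], -pos[gj]):
                        drop, local = gi, i
                    else:
                        drop, local = gj, j
                    keep[drop] = False
                    r2[local, :] = 0.0
                    r2[:, local] = 0.0
            if start + window_size >= len(where):
                break
            start += step
    return meta.loc[keep, "id"].tolist()


# ---------------------------------------------------------------------------
# relatedness

def estimate_pihat(dataset: GenotypeDataset, ids: list[str]) -> pd.DataFrame:
    """Method-of-moments IBD estimation for every sample pair.

    Observed identity-by-state counts are compared with their
    expectations given cohort allele frequencies to solve for
    P(IBD=0,1,2), truncated to the probability simplex;
    pi-hat = P(IBD=1)/2 + P(IBD=2).  Variants with any missing call are
    dropped (the pruned high-quality set has none by construction).
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least two samples")
    idx = dataset.variant_indexer(ids)
    d = dataset.dosages[:, idx]
    complete = ~np.isnan(d).any(axis=0)
    d = d[:, complete]
    m = d.shape[1]
    if m < 50:
        warnings.warn(
            f"only {m} complete pruned variants; pi-hat estimates will be imprecise",
            stacklevel=2,
        )
    if m == 0:
        raise ValueError("no complete variants available for IBD estimation")

    p = d.mean(axis=0) / 2.0
    q = 1.0 - p
    e_ibs0_ibd0 = float(np.sum(2.0 * p**2 * q**2))
    e_ibs1_ibd0 = float(np.sum(4.0 * p**3 * q + 4.0 * p * q**3))
    e_ibs2_ibd0 = float(np.sum(p**4 + q**4 + 4.0 * p**2 * q**2))
    e_ibs1_ibd1 = float(np.sum(2.0 * p**2 * q + 2.0 * p * q**2))
    e_ibs2_ibd1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    a0 = (d == 0.0).astype(np.float32)
    a1 = (d == 1.0).astype(np.float32)
    a2 = (d == 2.0).astype(np.float32)
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    ibs0 = a0 @ a2.T + a2 @ a0.T
    ibs1 = m - ibs2 - ibs0

    n = dataset.n_samples
    iu = np.triu_indices(n, k=1)
    n0 = ibs0[iu].astype(float)
    n1 = ibs1[iu].astype(float)
    n2 = ibs2[iu].astype(float)

    p0 = n0 / e_ibs0_ibd0
    p1 = (n1 - p0 * e_ibs1_ibd0) / e_ibs1_ibd1
    p2 = (n2 - p0 * e_ibs2_ibd0 - p1 * e_ibs2_ibd1) / m
    # truncate to the simplex
    p0 = np.clip(p0, 0.0, 1.0)
    p1 = np.clip(p1, 0.0, 1.0)
    p2 = np.clip(p2, 0.0, 1.0)
    total = p0 + p1 + p2
    p0, p1, p2 = p0 / total, p1 / total, p2 / total
    pihat = p1 / 2.0 + p2

    iids = pd.Categorical(dataset.samples["iid"])  # compact for large pair tables
    return pd.DataFrame(
        {
            "iid1": iids[iu[0]],
            "iid2": iids[iu[1]],
            "ibs0": n0,
            "ibs1": n1,
            "ibs2": n2,
            "p_ibd0": p0,
            "p_ibd1": p1,
            "p_ibd2": p2,
            "pihat": pihat,
        }
    )


def exclude_related(
    kinship: pd.DataFrame, pihat_max: float = 0.2, seed: int = 0
) -> list[str]:
    """Resolve pi-hat violations by removing one member of each
    offending pair, chosen by a seeded uniform draw; pairs are processed
    by descending pi-hat (ties by id) so the list is reproducible."""
    rng = np.random.default_rng([int(seed), 7])
    pairs = kinship.loc[kinship["pihat"] > pihat_max, ["iid1", "iid2", "pihat"]]
    pairs = pairs.sort_values(["pihat", "iid1", "iid2"], ascending=[False, True, True])
    removed: list[str] = []
    gone: set[str] = set()
    for iid1, iid2, _ in pairs.itertuples(index=False):
        if iid1 in gone or iid2 in gone:
            continue
        victim = iid1 if rng.random() < 0.5 else iid2
        removed.append(victim)
        gone.add(victim)
    return removed


# ---------------------------------------------------------------------------
# stratification PCA

def pca_stratification(
    dataset: GenotypeDataset,
    ids: list[str],
    n_pcs: int = 20,
    pc_outlier_sd: float = 6.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Principal components of the standardized genotype matrix and the
    |pc_outlier_sd|-SD outliers on the first ``n_pcs`` components
    (single pass, no recomputation after exclusion)."""
    idx = dataset.variant_indexer(ids)
    if len(idx) < n_pcs:
        raise ValueError(f"need at least n_pcs={n_pcs} pruned variants, got {len(idx)}")
    d = dataset.dosages[:, idx]
    col_mean = np.nanmean(d, axis=0)
    x = np.where(np.isnan(d), col_mean, d) - col_mean
    sd = x.std(axis=0)
    keep_cols = sd > 0
    if not keep_cols.any():
        raise ValueError("degenerate genotype matrix: all pruned variants are constant")
    x = x[:, keep_cols] / sd[keep_cols]

    k = min(n_pcs, min(x.shape) - 1) if min(x.shape) > 1 else 1
    if k < min(x.shape) // 4 and min(x.shape) > 50:
        # truncated SVD: only the leading components are ever used
        from scipy.sparse.linalg import svds

        v0 = np.ones(min(x.shape)) / np.sqrt(min(x.shape))
        u, s, _ = svds(x, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]
    else:
        u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :k] * s[:k]

    mu = pcs.mean(axis=0)
    sigma = pcs.std(axis=0, ddof=1)
    sigma[sigma == 0] = np.inf
    outlier_mask = (np.abs(pcs - mu) > pc_outlier_sd * sigma).any(axis=1)

    iids = dataset.samples["iid"].to_numpy()
    table = pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(k)])
    table.insert(0, "iid", iids)
    return table, iids[outlier_mask].tolist()


# ---------------------------------------------------------------------------
# orchestration

def run_qc(
    dataset: GenotypeDataset,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> tuple[GenotypeDataset, pd.DataFrame, QCReport]:
    """The full QC stack, in fixed order: variant filters -> sample
    filters -> high-quality subset -> LD pruning -> relatedness
    exclusion -> stratification PCA with outlier removal.

    Returns the cleaned dataset, per-sample PC coordinates (recomputed
    on the retained samples, for use as regression covariates) and the
    step-by-step QCReport.  Rerunning on the output removes nothing
    further except possibly new PCA outliers (documented
    non-idempotence).
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()

    out, steps = filter_variants(dataset, thresholds)
    for s in steps:
        report.add(s)
    out, steps = filter_samples(out, thresholds)
    for s in steps:
        report.add(s)

    hq = high_quality_subset(out, thresholds)
    pruned = ld_prune(
        out, hq, thresholds.prune_r2, thresholds.prune_window, thresholds.prune_step
    )
    report.add(
        QCStep(
            "hq_prune", "info",
            f"hq+r2<={thresholds.prune_r2}", [], out.n_samples, out.n_variants,
            note=f"{len(hq)} high-quality variants, {len(pruned)} after pruning",
        )
    )

    kinship = estimate_pihat(out, pruned)
    related = exclude_related(kinship, thresholds.pihat_max, seed)
    out = out.drop_samples(related)
    report.add(
        QCStep(
            "relatedness", "sample", f"pihat>{thresholds.pihat_max}",
            related, out.n_samples, out.n_variants,
        )
    )

    pcs, outliers = pca_stratification(out, pruned, thresholds.n_pcs, thresholds.pc_outlier_sd)
    out = out.drop_samples(outliers)
    report.add(
        QCStep(
            "pca_outlier", "sample",
            f"|{thresholds.pc_outlier_sd}SD| on PC1..PC{thresholds.n_pcs}",
            outliers, out.n_samples, out.n_variants,
        )
    )
    if outliers:
        # recompute covariate PCs on the retained samples
        pcs, _ = pca_stratification(out, pruned, thresholds.n_pcs, thresholds.pc_outlier_sd)
    return out, pcs, report
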