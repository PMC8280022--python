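"""Incremental-R2 evaluation, best-fit threshold selection, FDR control,
sex stratification, and a-priori power analysis.

The central statistic is the incremental R2: the increase in the
coefficient of determination when the polygenic score is added to an
ordinary-least-squares model that already contains the control
variables (sex, age and the first four stratification PCs in the
standard battery).  Its p-value is the two-sided test of the score
coefficient, equivalent to the 1-df F test of the R2 increase.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import PowerSpec
from .datatypes import AssociationResult, ScoreSet, results_to_frame
from .scoring import LabelScores

DEFAULT_COVARIATES = ("sex", "age", "PC1", "PC2", "PC3", "PC4")


# ---------------------------------------------------------------------------
# core OLS machinery

def _design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    x = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    X = np.column_stack([np.ones(len(x)), x])
    return X, ["const"] + names

def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def incremental_r2(
    phenotype: np.ndarray | pd.Series,
    pgs: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    *,
    phenotype_name: str = "",
    score_label: str = "",
    scheme: str = "",
    pt: float = np.nan,
    n_snps: int = 0,
    subgroup: str = "all",
) -> AssociationResult:
    """Base (covariates-only) and full (covariates + score) OLS fits on
    identical complete-case rows; the score is z-scored so ``beta_pgs``
    is in phenotype-SD-per-score-SD units.  A constant score yields
    incremental R2 = 0 with p = 1."""
    y = np.asarray(phenotype, dtype=float)
    s = np.asarray(pgs, dtype=float)
    c = covariates.reset_index(drop=True)
    complete = np.isfinite(y) & np.isfinite(s) & np.isfinite(c.to_numpy(dtype=float)).all(axis=1)
    y, s, c = y[complete], s[complete], c.loc[complete]
    n = len(y)
    X, names = _design(c)
    if n < X.shape[1] + 2:
        raise ValueError(f"only {n} complete cases for {X.shape[1]} base predictors")
    _check_rank(X, names)

    base = sm.OLS(y, X).fit()
    sd = s.std()
    if sd == 0:
        return AssociationResult(
            phenotype_name, score_label, scheme, pt, n_snps,
            float(base.rsquared), float(base.rsquared), 0.0, 0.0, 1.0,
            n_used=n, subgroup=subgroup,
        )
    z = (s - s.mean()) / sd
    full = sm.OLS(y, np.column_stack([X, z])).fit()
    return AssociationResult(
        phenotype_name, score_label, scheme, pt, n_snps,
        float(base.rsquared), float(full.rsquared),
        float(full.rsquared - base.rsquared),
        float(full.params[-1]), float(full.pvalues[-1]),
        n_used=n, subgroup=subgroup,
    )


def _incremental_r2_many(
    y: np.ndarray, scores: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vectorized incremental R2 of each score column against the same
    base design ``X`` (intercept included).  Uses the partial-correlation
    identity: inc R2 = (1 - R2_base) * r^2 with r the correlation of the
    residualized score and residualized phenotype."""
    q, _ = np.linalg.qr(X)
    ry = y - q @ (q.T @ y)
    rs = scores - q @ (q.T @ scores)
    ssy = float(ry @ ry)
    tss = float(((y - y.mean()) ** 2).sum())
    r2_base = 1.0 - ssy / tss if tss > 0 else 0.0
    num = rs.T @ ry
    den2 = (rs**2).sum(axis=0) * ssy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den2 > 0, num / np.sqrt(den2), 0.0)
    r = np.clip(r, -1.0, 1.0)
    inc = (1.0 - r2_base) * r**2
    df = len(y) - X.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where((rs**2).sum(axis=0) > 0, p, 1.0)
    return inc, p, r2_base


# ---------------------------------------------------------------------------
# best-fit threshold selection

def best_fit_select(
    sweep: ScoreSet,
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    **result_kw,
) -> tuple[float, AssociationResult, pd.DataFrame]:
    """Evaluate incremental R2 at every grid threshold and return the
    maximizing PT (ties broken toward the smallest PT), its full
    association result, and the whole PT-vs-R2 curve."""
    y = np.asarray(phenotype, dtype=float)
    c = covariates.reset_index(drop=True)
    complete = np.isfinite(y) & np.isfinite(c.to_numpy(dtype=float)).all(axis=1)
    X, names = _design(c.loc[complete])
    _check_rank(X, names)
    inc_unique, _, _ = _incremental_r2_many(
        y[complete], sweep.scores_unique[complete], X
    )
    count_to_col = {int(cnt): j for j, cnt in enumerate(sweep.unique_counts)}
    per_pt = inc_unique[[count_to_col[int(cnt)] for cnt in sweep.counts]]
    best = int(np.argmax(per_pt))  # first maximum -> smallest PT
    pt_star = float(sweep.pts[best])

    result = incremental_r2(
        phenotype,
        sweep._col_for_count(int(sweep.counts[best])),
        covariates,
        scheme="best",
        pt=pt_star,
        n_snps=int(sweep.counts[best]),
        **result_kw,
    )
    curve = pd.DataFrame(
        {"pt": sweep.pts, "n_snps": sweep.counts, "incremental_r2": per_pt}
    )
    return pt_star, result, curve


# ---------------------------------------------------------------------------
# multiple testing

def fdr_adjust(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up.

    Returns (adjusted p-values, per-rank critical values i*q/m in rank
    order, rejection flags).  Adjusted p-values are the usual monotone
    cumulative-minimum transform of p*(m/i)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * q  # rank m gives exactly q
    below = np.flatnonzero(ranked <= crit)
    k = below[-1] + 1 if len(below) else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = np.empty(m, dtype=bool)
    reject[order] = reject_sorted
    return adjusted, crit, reject


# ---------------------------------------------------------------------------
# the analysis battery

def _aligned_tables(
    scores_sample_ids: pd.Series,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Row-align phenotype and covariate tables to the score sample
    order via iid."""
    iids = scores_sample_ids.to_numpy()
    ph = phenotypes.set_index("iid").loc[iids].reset_index()
    cv = covariates.set_index("iid").loc[iids].reset_index()
    return ph, cv, iids


def run_battery(
    scores: Mapping[str, LabelScores],
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype_names: Sequence[str] | None = None,
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    q: float = 0.05,
    return_curves: bool = False,
):
    """Evaluate every score label x phenotype x scheme cell and adjust
    all raw p-values jointly by Benjamini-Hochberg.

    ``phenotypes`` and ``covariates`` must carry an ``iid`` column; rows
    are aligned to each ScoreSet's sample order.  At the standard scale
    (3 labels x 9 phenotypes x 3 schemes) this is the 81-analysis grid.
    """
    if phenotype_names is None:
        from .config import PHENOTYPES
        phenotype_names = [p for p in PHENOTYPES if p in phenotypes.columns]
    missing = [p for p in phenotype_names if p not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype column(s) not found: {missing}")

    results: list[AssociationResult] = []
    curves: dict[tuple[str, str], pd.DataFrame] = {}
    best_pts: dict[tuple[str, str], float] = {}
    for label, ls in scores.items():
        ph, cv, _ = _aligned_tables(ls.sweep.sample_ids, phenotypes, covariates)
        cov = cv[list(covariate_names)]
        for name in phenotype_names:
            y = ph[name]
            for scheme, ss in (("fixed", ls.fixed), ("all", ls.all)):
                results.append(
                    incremental_r2(
                        y, ss.scores_at(ss.pts[0]), cov,
                        phenotype_name=name, score_label=label, scheme=scheme,
                        pt=float(ss.pts[0]), n_snps=int(ss.counts[0]),
                    )
                )
            pt_star, res, curve = best_fit_select(
                ls.sweep, y, cov, phenotype_name=name, score_label=label
            )
            results.append(res)
            best_pts[(label, name)] = pt_star
            curves[(label, name)] = curve

    table = results_to_frame(results)
    table["p_adjusted"], _, table["rejected"] = fdr_adjust(table["p_raw"].to_numpy(), q)
    if return_curves:
        return table, best_pts, curves
    return table, best_pts


def sex_stratified_battery(
    scores: Mapping[str, LabelScores],
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    best_pts: Mapping[tuple[str, str], float],
    phenotype_names: Sequence[str] | None = None,
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    q: float = 0.05,
) -> pd.DataFrame:
    """Re-run the battery separately per sex.

    Control variables are age and the PCs (sex dropped); fixed and
    all-SNP schemes are re-evaluated per subgroup, while the best-fit
    scheme reuses the full-sample best-fit PT per (label, phenotype) --
    no re-selection inside subgroups.  Adjusted p-values form their own
    BH family across the stratified grid.
    """
    if phenotype_names is None:
        from .config import PHENOTYPES
        phenotype_names = [p for p in PHENOTYPES if p in phenotypes.columns]
    strat_covs = [c for c in covariate_names if c != "sex"]
    results: list[AssociationResult] = []
    for label, ls in scores.items():
        ph, cv, _ = _aligned_tables(ls.sweep.sample_ids, phenotypes, covariates)
        sex = cv["sex"].to_numpy()
        levels = np.unique(sex[np.isfinite(sex)])
        if len(levels) != 2:
            raise ValueError(f"expected exactly two sex levels, found {levels}")
        for level, tag in zip(levels, ("male", "female")):
            mask = sex == level
            cov = cv.loc[mask, strat_covs]
            for name in phenotype_names:
                y = ph.loc[mask, name]
                cells = [
                    ("fixed", ls.fixed.scores_at(ls.fixed.pts[0])[mask],
                     float(ls.fixed.pts[0]), int(ls.fixed.counts[0])),
                    ("all", ls.all.scores_at(ls.all.pts[0])[mask],
                     float(ls.all.pts[0]), int(ls.all.counts[0])),
                ]
                pt_star = float(best_pts[(label, name)])
                cells.append(
                    ("best", ls.sweep.scores_at(pt_star)[mask],
                     pt_star, ls.sweep.count_at(pt_star))
                )
                for scheme, s, pt, n_snps in cells:
                    results.append(
                        incremental_r2(
                            y, s, cov,
                            phenotype_name=name, score_label=label, scheme=scheme,
                            pt=pt, n_snps=n_snps, subgroup=tag,
                        )
                    )
    table = results_to_frame(results)
    table["p_adjusted"], _, table["rejected"] = fdr_adjust(table["p_raw"].to_numpy(), q)
    return table


# ---------------------------------------------------------------------------
# between-group comparison and simple tests

def _single_incremental_r2(y: np.ndarray, s: np.ndarray, X: np.ndarray) -> float:
    inc, _, _ = _incremental_r2_many(y, s[:, None], X)
    return float(inc[0])


def compare_incremental_r2(
    phenotype_a: np.ndarray,
    score_a: np.ndarray,
    covariates_a: pd.DataFrame,
    phenotype_b: np.ndarray,
    score_b: np.ndarray,
    covariates_b: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided bootstrap comparison of incremental R2 between groups.

    Individuals are resampled within each group; the p-value is the
    two-sided percentile test of delta = incR2_A - incR2_B against 0,
    with plus-one smoothing.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; the p-value will be coarse", stacklevel=2)
    rng = np.random.default_rng([int(seed), 11])

    def prep(y, s, c):
        y = np.asarray(y, dtype=float)
        s = np.asarray(s, dtype=float)
        c = c.reset_index(drop=True)
        ok = np.isfinite(y) & np.isfinite(s) & np.isfinite(c.to_numpy(dtype=float)).all(axis=1)
        X, _ = _design(c.loc[ok])
        return y[ok], s[ok], X

    ya, sa, Xa = prep(phenotype_a, score_a, covariates_a)
    yb, sb, Xb = prep(phenotype_b, score_b, covariates_b)
    delta = _single_incremental_r2(ya, sa, Xa) - _single_incremental_r2(yb, sb, Xb)

    boots = np.empty(n_boot)
    for b in range(n_boot):
        ia = rng.integers(0, len(ya), len(ya))
        ib = rng.integers(0, len(yb), len(yb))
        boots[b] = _single_incremental_r2(ya[ia], sa[ia], Xa[ia]) - _single_incremental_r2(
            yb[ib], sb[ib], Xb[ib]
        )
    n_le = int(np.sum(boots <= 0.0))
    n_ge = int(np.sum(boots >= 0.0))
    p = 2.0 * min((n_le + 1) / (n_boot + 1), (n_ge + 1) / (n_boot + 1))
    return float(delta), float(min(p, 1.0))


def sex_difference_test(values: np.ndarray | pd.Series, sex: np.ndarray | pd.Series):
    """Two-sample pooled-variance t test; df = n_total - 2.

    Groups are the two sex levels in ascending code order, and t is
    mean(first) - mean(second) over the pooled standard error.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(sex)
    ok = np.isfinite(v)
    v, g = v[ok], g[ok]
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, found {levels}")
    a, b = v[g == levels[0]], v[g == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


# ---------------------------------------------------------------------------
# a-priori power analysis

def regression_power(n: int, f2: float, u: int, alpha: float) -> float:
    """Power of the F test of R2 != 0 in multiple linear regression with
    ``u`` predictors at sample size ``n``: noncentral F with
    noncentrality f2*n and denominator df n - u - 1."""
    dfd = n - u - 1
    if dfd < 1:
        return 0.0
    crit = stats.f.ppf(1.0 - alpha, u, dfd)
    return float(1.0 - stats.ncf.cdf(crit, u, dfd, f2 * n))


def required_sample_size(spec: PowerSpec) -> int:
    """Smallest integer N whose F-test power meets the target."""
    lo = spec.u + 2
    if regression_power(lo, spec.f2, spec.u, spec.alpha) >= spec.power:
        return lo
    hi = lo
    while regression_power(hi, spec.f2, spec.u, spec.alpha) < spec.power:
        hi *= 2
        if hi > 100_000_000:
            raise ValueError("target power unreachable at any feasible sample size")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if regression_power(mid, spec.f2, spec.u, spec.alpha) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi
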