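"""Independent reference implementations used to cross-check the package.

Each oracle takes a deliberately different computational route from the
implementation it checks (closed-form log-gamma enumeration vs recurrence,
nested-loop scans vs vectorized passes, normal equations vs fitted models).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Levene-Haldane exact p by direct closed-form enumeration.

    log P(het = h | rare allele count, n) via log-gamma factorials,
    summed over all heterozygote counts whose probability does not
    exceed the observed one.
    """
    n = n_hom1 + n_het + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.searchsorted(hets, n_het)]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-10)].sum()))


def bh_sort_and_scan(p_values, q: float):
    """Literal Benjamini-Hochberg step-up: sort, scan for the largest
    rank with p(i) <= i*q/m, reject everything at or below it."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    k = 0
    for i in range(m):
        if ranked[i] <= (i + 1) * q / m:
            k = i + 1
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def greedy_clump_reference(ids, chrom, pos, p, r2_matrix, clump_r2, clump_kb):
    """Nested-loop re-implementation of p-ascending greedy clumping."""
    order = sorted(range(len(ids)), key=lambda i: (p[i], chrom[i], pos[i]))
    claimed: set[int] = set()
    retained: list[str] = []
    for i in order:
        if i in claimed:
            continue
        retained.append(ids[i])
        claimed.add(i)
        for j in range(len(ids)):
            if j in claimed:
                continue
            if (
                chrom[j] == chrom[i]
                and abs(pos[j] - pos[i]) <= clump_kb * 1000.0
                and r2_matrix[i, j] > clump_r2
            ):
                claimed.add(j)
    return retained


def ols_r2_normal_equations(y, X):
    """R-squared via the normal equations (X includes the intercept)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tss


def power_grid_search(f2: float, alpha: float, target: float, u: int, n_max: int = 5000) -> int:
    """Smallest N meeting the power target by linear scan over the
    noncentral-F power curve."""
    from scipy import stats

    for n in range(u + 2, n_max):
        dfd = n - u - 1
        crit = stats.f.ppf(1 - alpha, u, dfd)
        if 1.0 - stats.ncf.cdf(crit, u, dfd, f2 * n) >= target:
            return n
    raise AssertionError("no N found within grid")
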