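"""Polygenic-score construction: allele harmonization, LD clumping, and
weighted allele sums across p-value-threshold schemes.

Scores are raw weighted dosage sums (no allele-count division): every
downstream incremental-R2 statistic is invariant to linear rescaling,
and raw sums make the fine-grained threshold sweep a single cumulative
pass over p-sorted variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ThresholdScheme
from .datatypes import GenotypeDataset, ScoreSet, SummaryStatistics

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    sumstats: SummaryStatistics, dataset: GenotypeDataset
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Match summary statistics to dataset variants and express every
    weight on the dataset's A1 dosage.

    Matching is by variant id; effect alleles aligned directly, by
    allele swap (beta negated), or by strand complement; palindromic
    (A/T, C/G) variants are removed unconditionally; allele-inconsistent
    records are dropped.  Chromosome/position disagreements are counted
    but do not remove a match.  Returns the weight table (columns id,
    chrom, pos, beta, p, freq_a1) and a category-count report.
    """
    if len(sumstats) == 0 or dataset.n_variants == 0:
        raise ValueError("harmonize: empty input")
    ss = sumstats.table.set_index("id")
    var = dataset.variants.set_index("id")
    common = var.index.intersection(ss.index)
    report = {
        "matched_direct": 0,
        "matched_swapped": 0,
        "matched_complement": 0,
        "matched_complement_swapped": 0,
        "palindromic_removed": 0,
        "allele_mismatch": 0,
        "unmatched_sumstat": int(len(ss) - len(common)),
        "chrpos_mismatch": 0,
    }
    if len(common) == 0:
        raise ValueError("harmonize: no variant ids shared between inputs")

    rows = []
    freq_a1 = pd.Series(dataset.allele_freq(), index=dataset.variants["id"].to_numpy())
    for vid in common:
        a1, a2 = var.at[vid, "a1"], var.at[vid, "a2"]
        ea, oa = ss.at[vid, "effect_allele"], ss.at[vid, "other_allele"]
        if _is_palindromic(ea, oa) or _is_palindromic(a1, a2):
            report["palindromic_removed"] += 1
            continue
        beta = float(ss.at[vid, "beta"])
        if (ea, oa) == (a1, a2):
            report["matched_direct"] += 1
        elif (ea, oa) == (a2, a1):
            beta = -beta
            report["matched_swapped"] += 1
        else:
            cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
            if (cea, coa) == (a1, a2):
                report["matched_complement"] += 1
            elif (cea, coa) == (a2, a1):
                beta = -beta
                report["matched_complement_swapped"] += 1
            else:
                report["allele_mismatch"] += 1
                continue
        if "chrom" in ss.columns and "pos" in ss.columns:
            if (str(ss.at[vid, "chrom"]) != str(var.at[vid, "chrom"])
                    or int(ss.at[vid, "pos"]) != int(var.at[vid, "pos"])):
                report["chrpos_mismatch"] += 1
        rows.append(
            {
                "id": vid,
                "chrom": var.at[vid, "chrom"],
                "pos": int(var.at[vid, "pos"]),
                "beta": beta,
                "p": float(ss.at[vid, "p"]),
                "freq_a1": float(freq_a1[vid]) if np.isfinite(freq_a1[vid]) else 0.5,
            }
        )
    if not rows:
        raise ValueError("harmonize: no variants survived allele matching")
    weights = pd.DataFrame(rows)
    return weights, report


def _imputed_dosages(dataset: GenotypeDataset, idx: np.ndarray, freq: np.ndarray) -> np.ndarray:
    d = dataset.dosages[:, idx].copy()
    fill = np.broadcast_to(2.0 * freq, d.shape)
    nan = np.isnan(d)
    d[nan] = fill[nan]
    return d


def clump(
    weights: pd.DataFrame,
    dataset: GenotypeDataset,
    clump_r2: float = 0.1,
    clump_kb: float = 250.0,
    clump_p1: float = 1.0,
) -> list[str]:
    """Greedy p-ascending LD clumping.

    The most significant unclaimed variant becomes an index; every
    unclaimed variant on the same chromosome within ``clump_kb`` kb with
    genotype r^2 > ``clump_r2`` is claimed (removed).  Ties in p are
    broken by chromosome then position.  Returns retained ids, in the
    weight table's order.
    """
    w = weights.reset_index(drop=True)
    idx = dataset.variant_indexer(w["id"].tolist())
    d = dataset.dosages[:, idx]
    col_mean = np.nanmean(d, axis=0)
    x = np.where(np.isnan(d), col_mean, d) - col_mean
    norms = np.sqrt((x**2).sum(axis=0))
    norms[norms == 0] = 1.0
    x = x / norms

    order = np.lexsort((w["pos"].to_numpy(), w["chrom"].to_numpy(), w["p"].to_numpy()))
    chrom = w["chrom"].to_numpy()
    pos = w["pos"].to_numpy()
    p = w["p"].to_numpy()
    window = clump_kb * 1000.0

    state = np.zeros(len(w), dtype=np.int8)  # 0 free, 1 index, -1 claimed
    for i in order:
        if state[i] != 0 or p[i] > clump_p1:
            continue
        state[i] = 1
        near = np.flatnonzero(
            (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window) & (state == 0)
        )
        if len(near):
            r2 = (x[:, near].T @ x[:, i]) ** 2
            state[near[r2 > clump_r2]] = -1
    return w.loc[state == 1, "id"].tolist()


def score(
    dataset: GenotypeDataset, weights: pd.DataFrame, ids: list[str] | None = None
) -> np.ndarray:
    """Per-sample weighted allele sum over ``ids`` (default: all weights).

    Missing dosages are imputed with twice the cohort A1 frequency, so
    the score expectation is unbiased under missing-at-random calls.
    """
    w = weights if ids is None else weights[weights["id"].isin(set(ids))]
    known = w["id"].isin(set(dataset.variants["id"]))
    w = w[known]
    if len(w) == 0:
        return np.zeros(dataset.n_samples)
    idx = dataset.variant_indexer(w["id"].tolist())
    d = _imputed_dosages(dataset, idx, w["freq_a1"].to_numpy())
    return d @ w["beta"].to_numpy()


def score_over_thresholds(
    dataset: GenotypeDataset,
    weights: pd.DataFrame,
    scheme: ThresholdScheme,
    label: str = "",
) -> ScoreSet:
    """Scores at every threshold of the scheme's grid in one pass.

    Variants are p-sorted once and per-variant contributions cumulated,
    so the full ten-thousand-threshold sweep costs a single cumulative
    sum; thresholds sharing an inclusion count share a score column.
    """
    pts = scheme.grid()
    w = weights.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    idx = dataset.variant_indexer(w["id"].tolist())
    d = _imputed_dosages(dataset, idx, w["freq_a1"].to_numpy())
    contrib = d * w["beta"].to_numpy()
    prefix = np.cumsum(contrib, axis=1)

    counts = np.searchsorted(w["p"].to_numpy(), pts, side="right")
    unique_counts = np.unique(counts)
    cols = []
    for c in unique_counts:
        cols.append(np.zeros(dataset.n_samples) if c == 0 else prefix[:, c - 1])
    scores_unique = np.column_stack(cols) if cols else np.zeros((dataset.n_samples, 0))
    return ScoreSet(
        sample_ids=dataset.samples["iid"],
        pts=pts,
        counts=counts,
        unique_counts=unique_counts,
        scores_unique=scores_unique,
        label=label,
    )


@dataclass
class LabelScores:
    """The three threshold schemes of one score label."""

    label: str
    fixed: ScoreSet
    sweep: ScoreSet
    all: ScoreSet


def build_scores(
    dataset: GenotypeDataset,
    sumstats: SummaryStatistics,
    label: str = "",
    clump_variants: bool = True,
    clump_r2: float = 0.1,
    clump_kb: float = 250.0,
    fixed_pt: float = 0.05,
) -> tuple[LabelScores, dict[str, int]]:
    """Harmonize, optionally clump, and score under all three schemes."""
    weights, report = harmonize(sumstats, dataset)
    if clump_variants:
        retained = clump(weights, dataset, clump_r2=clump_r2, clump_kb=clump_kb)
        report["clumped_away"] = len(weights) - len(retained)
        weights = weights[weights["id"].isin(set(retained))].reset_index(drop=True)
    scores = LabelScores(
        label=label,
        fixed=score_over_thresholds(
            dataset, weights, ThresholdScheme(kind="fixed", fixed_pt=fixed_pt), label
        ),
        sweep=score_over_thresholds(dataset, weights, ThresholdScheme(kind="sweep"), label),
        all=score_over_thresholds(dataset, weights, ThresholdScheme(kind="all"), label),
    )
    return scores, report
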