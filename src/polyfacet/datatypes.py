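"""In-memory containers: genotypes, summary statistics, scores, QC report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid", "sex"]


@dataclass
class GenotypeDataset:
    """A sample x variant allele-dosage matrix plus metadata.

    ``dosages`` counts copies of A1 per call: values in {0, 1, 2} with
    NaN for missing.  ``variants`` has columns id/chrom/pos/a1/a2 (1-based
    positions, strictly increasing within a chromosome); ``samples`` has
    fid/iid/sex (sex coded 1=male, 2=female, 0=unknown, PLINK .fam style).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"samples table has {len(self.samples)} rows for {n} dosage rows")
        if len(self.variants) != m:
            raise ValueError(f"variants table has {len(self.variants)} rows for {m} columns")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate variant ids: {dups[:5]}")
        d = self.dosages
        ok = np.isnan(d) | (d == 0.0) | (d == 1.0) | (d == 2.0)
        if not ok.all():
            bad = d[~ok]
            raise ValueError(f"dosages must be 0/1/2/NaN; found {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> pd.Series:
        return self.samples["iid"]

    @property
    def variant_ids(self) -> pd.Series:
        return self.variants["id"]

    def variant_indexer(self, ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given variant ids (order preserved)."""
        lookup = pd.Series(np.arange(self.n_variants), index=self.variants["id"])
        missing = [v for v in ids if v not in lookup.index]
        if missing:
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return lookup.loc[list(ids)].to_numpy()

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask)
            d = d[sample_mask]
            samples = samples.loc[sample_mask]
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask)
            d = d[:, variant_mask]
            variants = variants.loc[variant_mask]
        return GenotypeDataset(d.copy(), variants.copy(), samples.copy())

    def drop_samples(self, iids: Iterable[str]) -> "GenotypeDataset":
        drop = set(iids)
        keep = ~self.samples["iid"].isin(drop).to_numpy()
        return self.subset(sample_mask=keep)

    def drop_variants(self, ids: Iterable[str]) -> "GenotypeDataset":
        drop = set(ids)
        keep = ~self.variants["id"].isin(drop).to_numpy()
        return self.subset(variant_mask=keep)

    def allele_freq(self) -> np.ndarray:
        """Cohort frequency of A1 per variant over non-missing calls
        (NaN where every call is missing)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.dosages.copy(), self.variants.copy(), self.samples.copy())


@dataclass
class SummaryStatistics:
    """Discovery-GWAS per-variant effect estimates used as score weights.

    ``table`` columns: id, chrom, pos, effect_allele, other_allele, beta
    (per effect-allele copy on the standardized discovery trait), se
    (optional, NaN allowed), p in (0, 1], n (optional discovery size).
    """

    table: pd.DataFrame

    REQUIRED = ["id", "effect_allele", "other_allele", "beta", "p"]

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"summary statistics missing column {col!r}")
        if t["id"].duplicated().any():
            raise ValueError("summary statistics contain duplicated variant ids")
        p = t["p"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect_allele must differ from other_allele")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline tries to recover."""

    causal_ids: list[str]
    true_betas: pd.Series            # per-variant standardized effect; 0 for non-causal
    true_score: np.ndarray           # per-sample latent genetic score (standardized)
    variance_shares: pd.DataFrame    # per phenotype: genetic/covariate/noise, rows sum to 1


@dataclass
class QCStep:
    """One filter of the QC stack and everything it removed."""

    name: str
    kind: str                        # 'variant' | 'sample' | 'info'
    threshold: str
    removed: list[str]
    n_samples_after: int
    n_variants_after: int
    note: str = ""


@dataclass
class QCReport:
    """Ordered record of all QC filters; every removed id appears in
    exactly one step."""

    steps: list[QCStep] = field(default_factory=list)

    def add(self, step: QCStep) -> None:
        self.steps.append(step)

    def removed_by(self, name: str) -> list[str]:
        return [i for s in self.steps if s.name == name for i in s.removed]

    def all_removed(self, kind: str) -> list[str]:
        return [i for s in self.steps if s.kind == kind for i in s.removed]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": s.name,
                "kind": s.kind,
                "threshold": s.threshold,
                "n_removed": len(s.removed),
                "removed_ids": ",".join(s.removed),
                "n_samples_after": s.n_samples_after,
                "n_variants_after": s.n_variants_after,
                "note": s.note,
            }
            for s in self.steps
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = []
        for s in self.steps:
            lines.append(
                f"{s.name:<18} ({s.kind:<7}) thr={s.threshold:<12} removed={len(s.removed):>5}"
                f"  -> {s.n_samples_after} samples / {s.n_variants_after} variants"
                + (f"  [{s.note}]" if s.note else "")
            )
        return "\n".join(lines)


@dataclass
class ScoreSet:
    """Per-sample polygenic scores across a grid of p-value thresholds.

    Scores for distinct thresholds that admit the same variant set are
    stored once: ``counts[t]`` gives the included-variant count at
    threshold ``pts[t]`` and indexes into the unique-count score columns.
    """

    sample_ids: pd.Series
    pts: np.ndarray                  # ascending thresholds
    counts: np.ndarray               # included variants per threshold
    unique_counts: np.ndarray        # sorted distinct counts
    scores_unique: np.ndarray        # n_samples x len(unique_counts)
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("included-variant count must be non-decreasing in PT")
        if not np.all(np.isfinite(self.scores_unique)):
            raise ValueError("scores must be finite")

    @property
    def n_thresholds(self) -> int:
        return len(self.pts)

    def _col_for_count(self, count: int) -> np.ndarray:
        j = np.searchsorted(self.unique_counts, count)
        if j >= len(self.unique_counts) or self.unique_counts[j] != count:
            raise KeyError(f"no score column for inclusion count {count}")
        return self.scores_unique[:, j]

    def scores_at(self, pt: float) -> np.ndarray:
        """Per-sample score at the grid threshold closest-below ``pt``."""
        t = np.searchsorted(self.pts, pt, side="right") - 1
        if t < 0:
            raise KeyError(f"threshold {pt} below the grid start {self.pts[0]}")
        return self._col_for_count(int(self.counts[t]))

    def count_at(self, pt: float) -> int:
        t = np.searchsorted(self.pts, pt, side="right") - 1
        if t < 0:
            raise KeyError(f"threshold {pt} below the grid start {self.pts[0]}")
        return int(self.counts[t])

    def to_frame(self) -> pd.DataFrame:
        """Materialize one column per threshold (use on small grids only)."""
        cols = {f"pt_{pt:g}": self._col_for_count(int(c)) for pt, c in zip(self.pts, self.counts)}
        return pd.DataFrame(cols, index=self.sample_ids.to_numpy())


@dataclass
class AssociationResult:
    """One incremental-R2 evaluation (phenotype x score x scheme)."""

    phenotype: str
    score_label: str
    scheme: str                      # 'fixed' | 'best' | 'all'
    pt: float
    n_snps: int
    r2_base: float
    r2_full: float
    incremental_r2: float
    beta_pgs: float
    p_raw: float
    p_adjusted: float = np.nan
    n_used: int = 0
    subgroup: str = "all"

    def as_dict(self) -> Mapping[str, object]:
        return {
            "phenotype": self.phenotype,
            "score_label": self.score_label,
            "scheme": self.scheme,
            "subgroup": self.subgroup,
            "pt": self.pt,
            "n_snps": self.n_snps,
            "r2_base": self.r2_base,
            "r2_full": self.r2_full,
            "incremental_r2": self.incremental_r2,
            "beta_pgs": self.beta_pgs,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "n_used": self.n_used,
        }


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
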