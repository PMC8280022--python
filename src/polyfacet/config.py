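"""Configuration objects shared across the pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: The nine cognitive measures of the battery, all oriented higher-is-better
#: (processing speed is sign-flipped at generation).
PHENOTYPES: tuple[str, ...] = (
    "general_intelligence",
    "verbal_intelligence",
    "numerical_intelligence",
    "figural_intelligence",
    "memory",
    "knowledge_ist",
    "knowledge_bowit",
    "processing_speed",
    "matrices",
)

N_PHENOTYPES = len(PHENOTYPES)


class ConfigError(ValueError):
    """Raised when a configuration field is outside its admissible range."""


def _as_vector(value, name: str) -> np.ndarray:
    """Broadcast a scalar or length-9 sequence to one value per phenotype."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(N_PHENOTYPES, float(arr))
    if arr.shape != (N_PHENOTYPES,):
        raise ConfigError(
            f"{name}: expected a scalar or {N_PHENOTYPES} values, got shape {arr.shape}"
        )
    return arr


# Standardized male-female mean differences per measure, calibrated so that
# two-sample t statistics at n~557 land near the magnitudes reported for
# this kind of cognitive battery (males higher on general/numerical
# intelligence and knowledge, females higher on memory, ~0 elsewhere).
DEFAULT_SEX_EFFECTS: tuple[float, ...] = (
    0.42,   # general_intelligence
    0.0,    # verbal_intelligence
    0.65,   # numerical_intelligence
    0.0,    # figural_intelligence
    -0.41,  # memory (females higher)
    0.88,   # knowledge_ist
    0.82,   # knowledge_bowit
    0.0,    # processing_speed
    0.19,   # matrices
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are the desk-scale study conditions: a 2000-sample,
    5000-variant cohort with block LD, a polygenic architecture whose
    latent score explains ``score_r2`` of each phenotype, and discovery
    summary statistics with sampling noise matching ``discovery_n``.
    """

    n_samples: int = 2000
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 50
    ld_decay: float = 0.6
    prop_causal: float = 0.2
    discovery_n: float = 250_000
    score_r2: float | Sequence[float] = 0.05
    battery_correlation: float = 0.3
    sex_effect: float | Sequence[float] = DEFAULT_SEX_EFFECTS
    age_effect: float | Sequence[float] = -0.15
    missing_rate: float = 0.002
    seed: int = 0
    blocks_per_chrom: int = 10
    bp_spacing: int = 1000

    def __post_init__(self) -> None:
        if not (isinstance(self.n_samples, (int, np.integer)) and self.n_samples >= 2):
            raise ConfigError(f"n_samples: must be an integer >= 2, got {self.n_samples!r}")
        if not (isinstance(self.n_variants, (int, np.integer)) and self.n_variants >= 1):
            raise ConfigError(f"n_variants: must be an integer >= 1, got {self.n_variants!r}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range: need 0 < low <= high <= 0.5, got {self.maf_range!r}")
        if self.ld_block_size < 1:
            raise ConfigError(f"ld_block_size: must be >= 1, got {self.ld_block_size!r}")
        if not (0 <= self.ld_decay < 1):
            raise ConfigError(f"ld_decay: must be in [0, 1), got {self.ld_decay!r}")
        if not (0 < self.prop_causal <= 1):
            raise ConfigError(f"prop_causal: must be in (0, 1], got {self.prop_causal!r}")
        if self.prop_causal * self.n_variants < 1:
            raise ConfigError("prop_causal: prop_causal * n_variants must be >= 1")
        if not (self.discovery_n > 1 or math.isinf(self.discovery_n)):
            raise ConfigError(f"discovery_n: must be > 1 (or inf), got {self.discovery_n!r}")
        for name in ("score_r2",):
            v = _as_vector(getattr(self, name), name)
            if np.any(v < 0) or np.any(v >= 1):
                raise ConfigError(f"{name}: each value must be in [0, 1)")
        if not (0 <= self.battery_correlation < 1):
            raise ConfigError(
                f"battery_correlation: must be in [0, 1), got {self.battery_correlation!r}"
            )
        _as_vector(self.sex_effect, "sex_effect")
        _as_vector(self.age_effect, "age_effect")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError(f"missing_rate: must be in [0, 1), got {self.missing_rate!r}")
        if self.blocks_per_chrom < 1:
            raise ConfigError(f"blocks_per_chrom: must be >= 1, got {self.blocks_per_chrom!r}")

    @property
    def score_r2_vector(self) -> np.ndarray:
        return _as_vector(self.score_r2, "score_r2")

    @property
    def sex_effect_vector(self) -> np.ndarray:
        return _as_vector(self.sex_effect, "sex_effect")

    @property
    def age_effect_vector(self) -> np.ndarray:
        return _as_vector(self.age_effect, "age_effect")


@dataclass(frozen=True)
class FailureSpec:
    """Counts of QC failures to inject into a clean simulated dataset.

    Injected samples are appended (duplicates, Mendelian offspring) or
    modified in place (high missingness, ancestry shift); injected variant
    failures overwrite existing columns.
    """

    n_duplicates: int = 0
    n_parent_offspring: int = 0
    n_high_missing_samples: int = 0
    n_hwe_violations: int = 0
    n_rare_variants: int = 0
    n_ancestry_outliers: int = 0
    high_missing_rate: float = 0.10
    # interpolation weight toward the mirrored allele frequency 1-p for
    # the ancestry-shifted subgroup; 1.0 = full mirror, which maximizes
    # the PC signal while leaving each sample's expected heterozygosity
    # (and hence the |F| filter) untouched
    ancestry_shift: float = 1.0
    rare_maf: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_duplicates",
            "n_parent_offspring",
            "n_high_missing_samples",
            "n_hwe_violations",
            "n_rare_variants",
            "n_ancestry_outliers",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")

    @property
    def total(self) -> int:
        return (
            self.n_duplicates
            + self.n_parent_offspring
            + self.n_high_missing_samples
            + self.n_hwe_violations
            + self.n_rare_variants
            + self.n_ancestry_outliers
        )


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds; defaults are the array-QC standards
    used throughout (PLINK-style strict inequalities)."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    variant_miss_max: float = 0.02
    sample_miss_max: float = 0.02
    het_abs_max: float = 0.2
    hq_hwe_p_min: float = 0.02
    hq_maf_min: float = 0.2
    hq_miss_max: float = 0.0
    prune_r2: float = 0.1
    prune_window: int = 50
    prune_step: int = 5
    pihat_max: float = 0.2
    n_pcs: int = 20
    pc_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "maf_min",
            "hwe_p_min",
            "variant_miss_max",
            "sample_miss_max",
            "hq_hwe_p_min",
            "hq_maf_min",
            "hq_miss_max",
            "prune_r2",
            "pihat_max",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name}: must be in [0, 1], got {v!r}")
        if self.n_pcs < 1:
            raise ConfigError(f"n_pcs: must be >= 1, got {self.n_pcs!r}")
        if self.pc_outlier_sd <= 0:
            raise ConfigError(f"pc_outlier_sd: must be > 0, got {self.pc_outlier_sd!r}")
        if self.prune_window < 2:
            raise ConfigError(f"prune_window: must be >= 2, got {self.prune_window!r}")
        if self.prune_step < 1:
            raise ConfigError(f"prune_step: must be >= 1, got {self.prune_step!r}")


# The best-fit sweep grid: 5e-8 + k*5e-5 for k >= 0, intersected with
# (0, 0.5] -- exactly 10,000 thresholds.
SWEEP_START = 5e-8
SWEEP_STOP = 0.5
SWEEP_STEP = 5e-5


@dataclass(frozen=True)
class ThresholdScheme:
    """A p-value-threshold scheme for SNP inclusion.

    kind='fixed' uses ``fixed_pt`` (default 0.05); kind='sweep' evaluates
    the full fine-grained grid; kind='all' includes every SNP (PT=1.00).
    """

    kind: str = "fixed"
    fixed_pt: float = 0.05
    sweep_start: float = SWEEP_START
    sweep_stop: float = SWEEP_STOP
    sweep_step: float = SWEEP_STEP
    all_pt: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "sweep", "all"):
            raise ConfigError(f"kind: must be 'fixed', 'sweep' or 'all', got {self.kind!r}")
        if self.kind == "fixed" and not (0 < self.fixed_pt <= 1):
            raise ConfigError(f"fixed_pt: must be in (0, 1], got {self.fixed_pt!r}")
        if self.kind == "sweep":
            if not (0 < self.sweep_start < self.sweep_stop):
                raise ConfigError("sweep: need 0 < sweep_start < sweep_stop")
            if self.sweep_step <= 0:
                raise ConfigError("sweep_step: must be > 0")

    def grid(self) -> np.ndarray:
        """The ascending array of thresholds this scheme evaluates."""
        if self.kind == "fixed":
            return np.array([self.fixed_pt])
        if self.kind == "all":
            return np.array([self.all_pt])
        n = int(math.floor((self.sweep_stop - self.sweep_start) / self.sweep_step)) + 1
        pts = self.sweep_start + self.sweep_step * np.arange(n + 1)
        pts = pts[(pts > 0) & (pts <= self.sweep_stop)]
        return pts


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power analysis for the F test of R2 != 0 in multiple
    linear regression (Cohen's f2 effect size)."""

    f2: float = 0.08
    alpha: float = 0.05
    power: float = 0.90
    u: int = 7

    def __post_init__(self) -> None:
        if self.f2 <= 0:
            raise ConfigError(f"f2: must be > 0, got {self.f2!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha: must be in (0, 1), got {self.alpha!r}")
        if not (0 < self.power < 1):
            raise ConfigError(f"power: must be in (0, 1), got {self.power!r}")
        if self.u < 1:
            raise ConfigError(f"u: must be >= 1, got {self.u!r}")

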