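"""QC stack: HWE exact test vs enumeration, stats vs brute-force tallies,
strict filter boundaries, pruning/kinship/PCA behavior, and attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import polyfacet as pf
from polyfacet.config import ConfigError, FailureSpec, QCThresholds
from polyfacet.genoqc import (
    estimate_pihat,
    exclude_related,
    filter_samples,
    filter_variants,
    high_quality_subset,
    hwe_exact_test,
    ld_prune,
    pca_stratification,
    run_qc,
    sample_stats,
    variant_stats,
)

from conftest import make_dataset
from oracles import hwe_enumeration


# ---------------------------------------------------------------------------
# HWE exact test

def test_hwe_monomorphic_returns_one():
    assert hwe_exact_test(50, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 50) == 1.0


@pytest.mark.parametrize(
    "counts",
    [(5, 0, 5), (25, 50, 25), (2, 3, 4), (0, 1, 0), (100, 50, 25), (1, 98, 1), (40, 0, 3)],
)
def test_hwe_matches_full_enumeration(counts):
    got = hwe_exact_test(*counts)
    want = hwe_enumeration(*counts)
    assert got == pytest.approx(want, rel=1e-12)


def test_hwe_modal_het_count_exceeds_half():
    assert hwe_exact_test(25, 50, 25) > 0.5


def test_hwe_rejects_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
)
def test_hwe_property_valid_and_matches_oracle(a, b, c):
    if a + b + c == 0:
        return
    p = hwe_exact_test(a, b, c)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(hwe_enumeration(a, b, c), rel=1e-10)


# ---------------------------------------------------------------------------
# per-variant / per-sample statistics

def test_variant_stats_monomorphic_column():
    ds = make_dataset(np.zeros((4, 1)))
    vs = variant_stats(ds)
    assert vs["maf"].iloc[0] == 0.0
    assert vs["missing_rate"].iloc[0] == 0.0


def test_variant_stats_with_missing_call():
    ds = make_dataset(np.array([[2.0], [1.0], [np.nan], [0.0]]))
    vs = variant_stats(ds)
    assert vs["maf"].iloc[0] == pytest.approx(0.5)
    assert vs["missing_rate"].iloc[0] == pytest.approx(0.25)


def test_variant_stats_equal_brute_force_tally():
    rng = np.random.default_rng(4)
    d = rng.integers(0, 3, size=(500, 200)).astype(float)
    d[rng.random((500, 200)) < 0.05] = np.nan
    ds = make_dataset(d)
    vs = variant_stats(ds)
    for j in rng.integers(0, 200, 40):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        freq = obs.sum() / (2 * len(obs))
        assert vs["maf"].iloc[j] == pytest.approx(min(freq, 1 - freq))
        assert vs["missing_rate"].iloc[j] == pytest.approx(np.isnan(col).mean())


def test_sample_stats_fully_homozygous_sample_has_f_one():
    d = np.array([[0.0, 2.0, 0.0, 2.0]] + [[1.0, 1.0, 1.0, 1.0]] * 5)
    ss = sample_stats(make_dataset(d))
    assert ss["het_f"].iloc[0] == pytest.approx(1.0)
    assert ss["missing_rate"].iloc[0] == 0.0


def test_sample_stats_f_near_zero_under_hwe():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=200, n_variants=5000, missing_rate=0.0, seed=8)
    )
    ss = sample_stats(ds)
    # |F| < 0.05 is a ~3-sigma band at 5000 variants: essentially all
    # samples sit inside it and none stray far
    assert (ss["het_f"].abs() < 0.05).mean() >= 0.95
    assert ss["het_f"].abs().max() < 0.1
    assert abs(ss["het_f"].mean()) < 0.01


# ---------------------------------------------------------------------------
# filters (strict inequalities)

def test_variant_at_exact_maf_threshold_is_retained():
    # one het among 50 samples: maf = 1/100 = 0.01 exactly -> kept ("< 0.01")
    d = np.zeros((50, 2))
    d[0, 0] = 1.0
    d[:, 1] = np.tile([0, 1, 2, 1, 0], 10)
    out, steps = filter_variants(make_dataset(d), QCThresholds())
    assert "v0" in set(out.variants["id"])


def test_variant_above_missingness_threshold_is_removed():
    d = np.column_stack([np.resize([0, 1, 2, 1.0], 50)] * 2)
    d[:2, 0] = np.nan  # 4% missing > 2%
    out, steps = filter_variants(make_dataset(d), QCThresholds())
    assert "v0" not in set(out.variants["id"])
    removed = {s.name: s.removed for s in steps}
    assert removed["variant_missing"] == ["v0"]


def test_all_missing_variant_is_flagged_for_removal():
    d = np.column_stack([np.resize([0, 1, 2, 1.0], 8)] * 2)
    d[:, 0] = np.nan
    out, steps = filter_variants(make_dataset(d), QCThresholds(maf_min=0.0))
    assert "v0" not in set(out.variants["id"])


def _boundary_het_dataset():
    # 6 all-het columns + 10 [0,2,2,0] columns; every cohort frequency is
    # 0.5, each sample has obs_het=6 and exp_het=8, so F = 0.25 exactly
    cols = [[1, 1, 1, 1]] * 6 + [[0, 2, 2, 0]] * 10
    return make_dataset(np.array(cols, dtype=float).T)


def test_sample_at_exact_het_threshold_is_retained():
    ds = _boundary_het_dataset()
    assert np.all(sample_stats(ds)["het_f"] == 0.25)
    out, _ = filter_samples(ds, QCThresholds(het_abs_max=0.25))
    assert out.n_samples == 4  # strict ">" keeps the boundary


def test_sample_het_filter_is_strict_above_threshold():
    ds = _boundary_het_dataset()
    with pytest.raises(ValueError, match="no samples remain"):
        filter_samples(ds, QCThresholds(het_abs_max=0.24))


def test_sample_at_exact_missingness_threshold_is_retained():
    d = np.column_stack([np.resize([0, 1, 2, 1.0], 6)] * 50)
    d[0, 0] = np.nan  # 1/50 = 0.02 exactly
    d[1, :3] = np.nan  # 0.06 > 0.02
    ds = make_dataset(d)
    out, steps = filter_samples(ds, QCThresholds(het_abs_max=5.0))
    kept = set(out.samples["iid"])
    assert "s0" in kept and "s1" not in kept


def test_sex_mismatch_step_is_logged_noop():
    ds = _boundary_het_dataset()
    _, steps = filter_samples(ds, QCThresholds(het_abs_max=0.5))
    sex_step = [s for s in steps if s.name == "sex_mismatch"][0]
    assert sex_step.removed == [] and "not evaluated" in sex_step.note


# ---------------------------------------------------------------------------
# high-quality subset

def test_high_quality_subset_matches_brute_force_scan():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=200, n_variants=300, missing_rate=0.01, seed=6)
    )
    thr = QCThresholds()
    got = set(high_quality_subset(ds, thr))
    vs = variant_stats(ds)
    want = {
        row.id
        for row in vs.itertuples(index=False)
        if row.hwe_p > 0.02 and row.maf > 0.2 and row.missing_rate <= 0.0
    }
    assert got == want


def test_variant_with_one_missing_call_is_excluded_from_hq():
    d = np.column_stack([np.resize([0, 1, 2, 1.0, 0, 1, 2, 1, 1, 1], 20)] * 2)
    d[0, 0] = np.nan
    ids = high_quality_subset(make_dataset(d), QCThresholds())
    assert "v0" not in ids and "v1" in ids


# ---------------------------------------------------------------------------
# LD pruning

def test_duplicate_columns_prune_to_one():
    rng = np.random.default_rng(0)
    col = rng.integers(0, 3, 100).astype(float)
    other = rng.integers(0, 3, 100).astype(float)
    ds = make_dataset(np.column_stack([col, col, other]))
    kept = ld_prune(ds, prune_r2=0.1)
    assert sum(v in kept for v in ("v0", "v1")) == 1


def test_independent_variants_survive_pruning():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=5000, n_variants=100, ld_decay=0.0,
                            missing_rate=0.0, seed=12)
    )
    kept = ld_prune(ds, prune_r2=0.1)
    assert len(kept) == 100


def test_prune_postcondition_no_retained_pair_exceeds_r2():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=400, n_variants=300, ld_decay=0.85,
                            missing_rate=0.0, seed=12)
    )
    window = 50
    kept = ld_prune(ds, prune_r2=0.1, window_size=window, step=5)
    idx = ds.variant_indexer(kept)
    d = ds.dosages[:, idx]
    x = (d - d.mean(0)) / d.std(0)
    chrom = ds.variants.iloc[idx]["chrom"].to_numpy()
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if idx[b] - idx[a] > window - 5:
                break
            if chrom[a] != chrom[b]:
                continue
            r2 = (x[:, a] @ x[:, b] / len(x)) ** 2
            assert r2 <= 0.1 + 1e-9


def test_prune_window_validation():
    ds = make_dataset(np.zeros((4, 3)))
    with pytest.raises(ConfigError, match="window"):
        ld_prune(ds, window_size=1)


# ---------------------------------------------------------------------------
# relatedness

@pytest.fixture(scope="module")
def kinship_setting():
    cfg = pf.SimulationConfig(n_samples=120, n_variants=2200, ld_decay=0.0,
                              maf_range=(0.2, 0.5), missing_rate=0.0, seed=19)
    ds = pf.simulate_genotypes(cfg)
    out, manifest = pf.inject_qc_failures(
        ds, FailureSpec(n_duplicates=1, n_parent_offspring=1, seed=19)
    )
    return out, manifest


def test_duplicate_pair_pihat_near_one(kinship_setting):
    ds, manifest = kinship_setting
    k = estimate_pihat(ds, ds.variants["id"].tolist())
    dup = manifest[manifest["kind"] == "duplicate"].iloc[0]
    pair = k[
        (k["iid1"].astype(str).isin([dup["id"], dup["partner"]]))
        & (k["iid2"].astype(str).isin([dup["id"], dup["partner"]]))
    ]
    assert pair["pihat"].iloc[0] >= 0.95


def test_parent_offspring_pihat_near_half(kinship_setting):
    ds, manifest = kinship_setting
    k = estimate_pihat(ds, ds.variants["id"].tolist())
    po = manifest[manifest["kind"] == "parent_offspring"].iloc[0]
    parents = po["partner"].split(";")
    for parent in parents:
        pair = k[
            (k["iid1"].astype(str).isin([po["id"], parent]))
            & (k["iid2"].astype(str).isin([po["id"], parent]))
        ]
        assert 0.4 <= pair["pihat"].iloc[0] <= 0.6


def test_unrelated_pairs_pihat_small(kinship_setting):
    ds, manifest = kinship_setting
    flagged = set(manifest["id"]) | {p for s in manifest["partner"] for p in s.split(";") if p}
    k = estimate_pihat(ds, ds.variants["id"].tolist())
    unrelated = k[
        ~k["iid1"].astype(str).isin(flagged) & ~k["iid2"].astype(str).isin(flagged)
    ]
    assert unrelated["pihat"].iloc[0] <= 0.1
    assert (unrelated["pihat"] <= 0.1).mean() > 0.99


def test_pihat_warns_on_few_variants():
    ds = make_dataset(np.column_stack([np.resize([0, 1, 2, 1.0], 6)] * 10))
    with pytest.warns(UserWarning, match="imprecise"):
        estimate_pihat(ds, ds.variants["id"].tolist())


def test_exclude_related_contracts():
    k = pd.DataFrame(
        {"iid1": ["a", "c"], "iid2": ["b", "d"], "pihat": [0.99, 0.05]}
    )
    removed = exclude_related(k, 0.2, seed=1)
    assert len(removed) == 1 and removed[0] in ("a", "b")
    assert exclude_related(k, 0.2, seed=1) == removed  # deterministic
    assert exclude_related(k[k["pihat"] < 0.2], 0.2, seed=1) == []


# ---------------------------------------------------------------------------
# stratification PCA

def test_pc_columns_are_orthogonal(small_study):
    ds = small_study.dataset
    ids = ds.variants["id"].tolist()[:200]
    pcs, _ = pca_stratification(ds, ids, n_pcs=10)
    x = pcs[[c for c in pcs.columns if c.startswith("PC")]].to_numpy()
    gram = x.T @ x
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()


def test_homogeneous_cohort_has_no_pc_outliers():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=300, n_variants=500, missing_rate=0.0, seed=14)
    )
    _, outliers = pca_stratification(ds, ds.variants["id"].tolist(), n_pcs=20)
    assert outliers == []


def test_ancestry_shifted_subgroup_is_flagged():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=400, n_variants=2000, missing_rate=0.0, seed=15)
    )
    out, manifest = pf.inject_qc_failures(ds, FailureSpec(n_ancestry_outliers=4, seed=15))
    shifted = set(manifest.loc[manifest["kind"] == "ancestry", "id"])
    pruned = ld_prune(out, high_quality_subset(out, QCThresholds()))
    _, outliers = pca_stratification(out, pruned, n_pcs=20)
    assert shifted <= set(outliers)


def test_pca_requires_enough_variants():
    ds = make_dataset(np.column_stack([np.resize([0, 1, 2, 1.0], 6)] * 4))
    with pytest.raises(ValueError, match="n_pcs"):
        pca_stratification(ds, ds.variants["id"].tolist(), n_pcs=10)


# ---------------------------------------------------------------------------
# orchestration

def test_run_qc_clean_dataset_survives():
    # enough variants that ~2000 markers survive pruning: pi-hat noise
    # then stays well below the 0.2 relatedness threshold
    ds = pf.simulate_genotypes(pf.SimulationConfig(n_samples=400, n_variants=6000, seed=44))
    clean, pcs, report = run_qc(ds, seed=44)
    assert clean.n_samples == ds.n_samples
    assert clean.n_variants >= 0.95 * ds.n_variants
    assert len(pcs) == clean.n_samples


def test_run_qc_vacuous_thresholds_leave_dataset_unchanged():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=150, n_variants=2000, missing_rate=0.0, seed=45)
    )
    thr = QCThresholds(
        maf_min=0.0, hwe_p_min=0.0, variant_miss_max=1.0, sample_miss_max=1.0,
        het_abs_max=1.0, pihat_max=1.0, pc_outlier_sd=100.0,
    )
    clean, _, report = run_qc(ds, thr, seed=0)
    assert clean.n_samples == ds.n_samples and clean.n_variants == ds.n_variants


def test_run_qc_attributes_each_injected_failure_to_its_filter():
    ds = pf.simulate_genotypes(
        pf.SimulationConfig(n_samples=400, n_variants=6000, missing_rate=0.0, seed=46)
    )
    spec = FailureSpec(
        n_duplicates=1, n_parent_offspring=1, n_high_missing_samples=1,
        n_hwe_violations=1, n_rare_variants=1, n_ancestry_outliers=3, seed=46,
    )
    injected, manifest = pf.inject_qc_failures(ds, spec)
    clean, _, report = run_qc(injected, seed=46)

    by_kind = {k: set(g["id"]) for k, g in manifest.groupby("kind")}
    assert by_kind["rare_variant"] <= set(report.removed_by("variant_maf"))
    assert by_kind["hwe_violation"] <= set(report.removed_by("variant_hwe"))
    assert by_kind["high_missing"] <= set(report.removed_by("sample_missing"))
    assert by_kind["ancestry"] <= set(report.removed_by("pca_outlier"))

    related_removed = set(report.removed_by("relatedness"))
    dup = manifest[manifest["kind"] == "duplicate"].iloc[0]
    assert len(related_removed & {dup["id"], dup["partner"]}) == 1
    po = manifest[manifest["kind"] == "parent_offspring"].iloc[0]
    family = {po["id"]} | set(po["partner"].split(";"))
    assert related_removed <= {dup["id"], dup["partner"]} | family

    # nothing else was removed by any step
    implicated = set(manifest["id"]) | {dup["partner"]} | family
    assert set(report.all_removed("sample")) <= implicated
    assert set(report.all_removed("variant")) == by_kind["rare_variant"] | by_kind["hwe_violation"]


def test_qc_report_accounting_is_exact(small_study):
    ds, manifest = pf.inject_qc_failures(
        small_study.dataset, FailureSpec(n_duplicates=1, n_high_missing_samples=1, seed=2)
    )
    clean, _, report = run_qc(ds, seed=2)
    assert ds.n_samples - clean.n_samples == len(report.all_removed("sample"))
    assert ds.n_variants - clean.n_variants == len(report.all_removed("variant"))
    all_ids = report.all_removed("sample") + report.all_removed("variant")
    assert len(all_ids) == len(set(all_ids))  # each id removed by exactly one step
    frame = report.to_frame()
    assert frame["n_samples_after"].is_monotonic_decreasing
    assert frame["n_variants_after"].is_monotonic_decreasing
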