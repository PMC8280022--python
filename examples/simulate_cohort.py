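"""Simulate a study cohort with known ground truth.

Generates genotypes with block LD, three discovery summary-statistic
sets (intelligence / cognitive performance / educational attainment
analogs, differing only in discovery sampling noise), and the
nine-measure cognitive battery.
"""

import numpy as np

import polyfacet as pf

cfg = pf.SimulationConfig(n_samples=500, n_variants=2000, score_r2=0.05, seed=1)
study = pf.simulate_study(cfg)

ds = study.dataset
print(f"cohort: {ds.n_samples} samples x {ds.n_variants} variants")
print(f"allele frequencies span {ds.allele_freq().min():.3f}-{ds.allele_freq().max():.3f}")
print(f"causal variants: {len(study.truth.causal_ids)} "
      f"({100 * len(study.truth.causal_ids) / ds.n_variants:.0f}% of all)")

for label, ss in study.sumstats.items():
    n_gw = int((ss.table['p'] < 5e-8).sum())
    print(f"{label}-GWAS (N={ss.table['n'].iloc[0]:,}): "
          f"{n_gw} genome-wide significant variants")

print("\nphenotype battery (per-measure variance decomposition):")
print(study.truth.variance_shares.round(3).to_string())
print("\nEach measure has unit variance; the 'genetic' share is the")
print("fraction a perfect polygenic score could explain.")

corr = np.corrcoef(study.phenotypes[list(pf.PHENOTYPES)].to_numpy().T)
off = corr[~np.eye(9, dtype=bool)]
print(f"mean between-measure correlation: {off.mean():.2f} "
      f"(shared factor target {cfg.battery_correlation})")
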