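"""Polygenic scores under three threshold schemes and their predictive
power per cognitive measure.

Builds clumping+thresholding scores from simulated discovery GWAS,
evaluates incremental R2 (covariates: sex, age, four ancestry PCs) for
every label x phenotype x scheme cell, and adjusts the whole family of
p-values by Benjamini-Hochberg.
"""

import polyfacet as pf
from polyfacet.evalstats import run_battery
from polyfacet.pipeline import render_report
from polyfacet.scoring import build_scores

cfg = pf.SimulationConfig(n_samples=800, n_variants=3000, score_r2=0.05, seed=5)
study = pf.simulate_study(cfg)

clean, pcs, _ = pf.run_qc(study.dataset, seed=5)
scores = {}
for label, sumstats in study.sumstats.items():
    scores[label], report = build_scores(clean, sumstats, label=label)
    print(f"{label}: {report['matched_direct']} matched, "
          f"{report['clumped_away']} removed by clumping")

covariates = pcs[["iid", "PC1", "PC2", "PC3", "PC4"]].merge(
    study.phenotypes[["iid", "sex", "age"]], on="iid"
)
table, best_pts = run_battery(scores, study.phenotypes, covariates)

print(f"\n{len(table)} analyses "
      f"({table['score_label'].nunique()} labels x 9 measures x 3 schemes)\n")
print(render_report(table))
print("\nbest-fit thresholds per (label, measure):")
for (label, name), pt in sorted(best_pts.items()):
    print(f"  {label:>3} {name:<24} PT* = {pt:g}")
print("\nBest-fit R2 always dominates the fixed and all-SNP schemes on the")
print("same data (it maximizes over a grid containing them) - which is why")
print("the non-fit PT=1.00 column is the honest companion to report.")
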