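"""A-priori sample-size estimation for the association analyses.

How many participants are needed to detect a small-to-medium effect
(Cohen's f2 = 0.08) in a multiple regression with 7 predictors (score +
sex + age + four ancestry PCs) at alpha = 0.05 with 90% power?  The F
test of R2 != 0 uses the noncentral F distribution with noncentrality
f2 * N.
"""

from polyfacet.config import PowerSpec
from polyfacet.evalstats import regression_power, required_sample_size

spec = PowerSpec(f2=0.08, alpha=0.05, power=0.90, u=7)
n = required_sample_size(spec)
print(f"required N = {n}")
print(f"power at N={n}:   {regression_power(n, spec.f2, spec.u, spec.alpha):.4f}")
print(f"power at N={n - 1}: {regression_power(n - 1, spec.f2, spec.u, spec.alpha):.4f}")
print("\nf2 = 0.08 corresponds to the score explaining ~7.4% of variance")
print("(f2 = R2/(1-R2)); a deeply phenotyped cohort of a few hundred is enough.")
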