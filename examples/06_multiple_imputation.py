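"""Handle missing-at-random data: chained-PMM imputation + Rubin pooling.

A cohort degraded to ~28% missingness is completed m times; the tobit sex
coefficient is estimated on each completed dataset and pooled, with the
between-imputation spread widening the final interval.
"""

import numpy as np

import genderpaths as gp

cfg = gp.GeneratorConfig(seed=4, missing_rate=0.28)
degraded = gp.generate_cohort(cfg)
print(f"missing cells: {int(degraded.isna().sum().sum())}")

per_imp = []
for c in gp.impute(degraded, m=10, seed=9):
    X = np.column_stack(
        [np.ones(len(c)), (c.sex == "female").to_numpy(float),
         c.age.to_numpy(float) - c.age.mean()]
    )
    fit = gp.fit_tobit(X, c.cesd.to_numpy(float))
    per_imp.append((fit.beta[1], fit.se[1]))

pe = gp.pool(per_imp)
print(
    f"pooled female B = {pe.qbar:.2f}, 95% CI ({pe.ci95[0]:.2f}; {pe.ci95[1]:.2f})\n"
    f"within-variance W = {pe.W:.3f}, between-variance B = {pe.B:.3f}, "
    f"total T = {pe.T:.3f}, df = {pe.df:.1f}"
)
# T >= W always: the pooled interval honestly reflects the extra
# uncertainty the missing data introduce.
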