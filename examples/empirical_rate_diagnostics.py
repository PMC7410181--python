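"""Reconstruct the rate constants k1(t), k3(t) from observations.

Inverts the pool balance equations on observation-derived carbon pools
(local-regression derivatives) and regresses the empirical k1 on the
relative growth rate per treatment — the diagnostic that motivates modelling
k1 as proportional to RGR (R^2 near 1) with treatment-dependent slopes that
track fruit water content.
"""

import numpy as np

from tomsugar import synth
from tomsugar.rates import build_pool_series, rate_diagnostics

study = synth.generate_study(seed=1)
datasets, trajs = synth.assemble_datasets(study, "cherry", use_fitted_growth=True)

series = {}
for obs, traj in datasets:
    ages = np.unique(obs.age_d)
    ss = np.array([obs.ss[obs.age_d == a].mean() for a in ages])
    st = np.array([obs.st[obs.age_d == a].mean() for a in ages])
    series[obs.name] = build_pool_series(ages, ss, st, traj)

table, reg = rate_diagnostics(series, trajs, k2_assumed=0.5)
print(table.head(8).round(4).to_string(index=False))
print("\nk1 ~ RGR per treatment (slope estimates the lambda coefficient):")
print(reg.round(3).to_string(index=False))
print("\nHigh R^2 supports the linear k1-RGR law; slope differences between")
print("treatments co-vary with fruit water content, motivating the")
print("water-content-modulated variant of the rate laws.")
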