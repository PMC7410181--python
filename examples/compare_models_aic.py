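"""Compare the plain and water-content model variants by multivariate AIC.

Calibrates both variants on the same synthetic cherry-type study (whose data
were generated WITH water-content effects) and reports the per-data-set and
mean AIC plus the four RRMSE goodness-of-fit statistics.  The water-content
variant should achieve the smaller mean AIC despite its three extra
parameters.
"""

import warnings

import numpy as np

from tomsugar import synth
from tomsugar.calibration import CriterionObjective, GAConfig, bounds_array, ga_optimize, polish
from tomsugar.core import ModelParameters, Variant
from tomsugar.evaluation import evaluate_fit

warnings.simplefilter("ignore")
study = synth.generate_study(seed=4)
datasets, _ = synth.assemble_datasets(study, "cherry", use_fitted_growth=True)
config = GAConfig(stall_generations=20, max_generations=50, stall_tol=1e-3)

for variant in (Variant.SUGAR, Variant.SUGAR_WC):
    objective = CriterionObjective(datasets, variant)
    bounds = bounds_array(variant)
    best_x, best_f = None, np.inf
    for r in range(3):
        res = ga_optimize(objective, bounds, config, seed=np.random.SeedSequence([4, r]))
        if res.criterion < best_f:
            best_f, best_x = res.criterion, res.x
    best_x, best_f = polish(objective, best_x, bounds)
    report = evaluate_fit(datasets, [ModelParameters.from_free(best_x, variant)])
    print(f"\n=== {variant.value} (criterion {best_f:.1f}) ===")
    print(report.round(3).to_string())

print("\nSmaller AIC wins: the penalty for the three extra water-content")
print("parameters is (2*3*2)/n per data set, far less than the residual")
print("improvement they buy on water-content-driven data.")
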