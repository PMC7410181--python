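"""Virtual water-content experiment: C, WS, CWS and WSC scenarios.

Perturbs only the water content entering the rate laws (2 percentage points,
applied over the whole season or only the early/late window) while keeping
the growth curve fixed, and prints where the carbon goes.  Total carbon is
identical across scenarios — the perturbation repartitions carbon between
sugars, starch and other compounds and changes concentrations through
dehydration, but cannot create or destroy carbon.
"""

import numpy as np

from tomsugar import initial_state, synth
from tomsugar.scenarios import build_scenarios, run_scenarios

template = synth.large_template()
temp = synth.generate_temperature(synth.ClimateConfig(), seed=1)
traj = synth.true_trajectory(template, temp)
init = initial_state(template.init_ss, template.init_st, float(traj.dw[0]))

scen = build_scenarios(traj, delta=2.0, switch_age_d=45.0)
runs = run_scenarios(scen, [template.true_params], init)

harvest = -1
print("scenario   Csol_end  Csta_end  Coth_end   total   SSC_end  STC_end")
for name in ("C", "WS", "CWS", "WSC"):
    csol = runs.csol[name][0, harvest]
    csta = runs.csta[name][0, harvest]
    coth = runs.coth[name][0, harvest]
    print(f"{name:8s} {csol:9.3f} {csta:9.3f} {coth:9.3f} "
          f"{csol + csta + coth:8.3f} {runs.ssc[name][0, harvest]:8.2f} "
          f"{runs.stc[name][0, harvest]:8.2f}")

during = traj.t <= 45.0 * 24.0
gain = runs.csta["WS"][0, during] - runs.csta["C"][0, during]
print(f"\nmean starch gain under continuous stress (early window): {gain.mean():.3f} g C")
print("For this large-fruited genotype (gamma > 0) lower water content diverts")
print("carbon into starch at every stage - even the late-only stress (CWS)")
print("repartitions sugars into starch - and the smaller fresh weight under")
print("stress additionally concentrates both solutes (dehydration effect).")
print("For a cherry-type truth (gamma ~ 0) the late-stress response is almost")
print("entirely dilution/dehydration instead.")
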