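"""Fit Gompertz growth curves and the water-content boundary from raw data.

Generates noisy fresh/dry-weight observations for one genotype, refits the
growth curves by nonlinear least squares, computes thermal time from the
hourly climate and fits the upper boundary of water content from the pooled
per-date maxima — everything the carbon model needs as input.
"""

import numpy as np

from tomsugar import degree_days, fit_gompertz, fit_wcmax, synth, water_content

template = synth.large_template()
temp = synth.generate_temperature(synth.ClimateConfig(), seed=2)
obs = synth.generate_growth(template, cv=0.05, replicates=4, seed=2)

t_h = obs["age_d"].to_numpy() * 24.0
fw_fit = fit_gompertz(t_h, obs["fw_g"].to_numpy())
dw_fit = fit_gompertz(t_h, obs["dw_g"].to_numpy())
print("fresh weight:  a=%.1f g  b=%.2f  c=%.5f /h   (true a=%.1f)"
      % (fw_fit.a, fw_fit.b, fw_fit.c, template.fw.a))
print("dry weight:    a=%.2f g  b=%.2f  c=%.5f /h   (true a=%.2f)"
      % (dw_fit.a, dw_fit.b, dw_fit.c, template.dw.a))

dd_hourly = degree_days(temp)
ages = np.unique(obs["age_d"])
dd_dates = np.interp(ages * 24.0, np.arange(temp.size), dd_hourly)
wc = water_content(obs["fw_g"].to_numpy(), obs["dw_g"].to_numpy())
pooled = [wc[obs["age_d"].to_numpy() == a] for a in ages]
boundary = fit_wcmax(dd_dates, pooled)
print("WCmax boundary: asymptote %.1f%%, deficit %.1f%%, rate %.4f per dd"
      % (boundary.p_inf, boundary.delta, boundary.r))
print("season thermal time: %.0f degree-days over %d days"
      % (dd_hourly[-1], temp.size // 24))
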