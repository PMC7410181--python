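# Methods

## The model

A growing tomato fruit is described by three carbon pools (g C per fruit):
soluble sugars `Csol` (glucose + fructose + sucrose treated as one pool),
starch `Csta`, and all other compounds `Coth` (cell walls, organic acids,
proteins, ...).  Carbon enters by phloem unloading and leaves by respiration;
import is estimated as growth carbon plus respiration, so respiration cancels
and the state equations are

```
dCsol/dt = c_DW · dDW/dt + k2·Csta − (k1(t)+k3(t))·Csol
dCsta/dt = k3(t)·Csol − k2·Csta
dCoth/dt = k1(t)·Csol
```

The three right-hand sides sum identically to `c_DW·dDW/dt`, so total pool
carbon equals `c_DW·DW(t)` up to quadrature error — the package's central
invariant, tested at 1e-6 relative.

Constants: `c_DW = 0.44` g C per g dry weight (tomato fruit), and the
conversion factors `c_sol = 0.400`, `c_sta = 0.444` g C per g are *computed*
from the hexose formula C6H12O6 and the anhydroglucose repeat unit (C6H10O5)n
(`constants.carbon_mass_fraction`), not hard-coded folklore.

Starch breakdown (`k2`, h⁻¹) is constant over development.  The two
synthesis-side rate constants are driven by development:

* plain variant — `k1 = λ·RGR`, `k3 = k30 / (1 + exp((DD−u)/τ))`,
  with RGR the relative growth rate of dry weight (h⁻¹), DD thermal time
  (degree-days above 5.7 °C), `u` the sigmoid midpoint and `τ` its width;
* water-content variant — each of the three places where water could act is
  given an exponential factor in the gap between the fruit's water content
  and its developmental upper boundary, `g(t) = WCmax(DD) − WC(t)`
  (percentage points of fresh weight):

```
k1 = λ·exp(α·g) · RGR^exp(β·g)
k3 = k30·exp(γ·g) / (1 + exp((DD−u)/τ))
```

With α=β=γ=0 the water-content variant reduces *bitwise* to the plain one
(same code path; the kernel always evaluates the general expressions).

## Numerics

The system is linear in the state with time-varying coefficients and is
integrated by fixed-step classical RK4 at 1 h.  Inputs at step midpoints are
taken analytically from the fitted Gompertz curves when the trajectory was
built from curves (linear interpolation otherwise), which keeps the
total-carbon quadrature at Simpson accuracy.  The kernel (numba-compiled) is
vectorised over whole matrices of parameter sets; this is what makes
population-based calibration affordable on one CPU.

Pools are never clipped: a pool falling below −1e-9 (scaled by total carbon)
or overflowing marks the parameter set infeasible.  During calibration such
sets receive a 1e12 penalty; the public `integrate` raises instead.  Large
`k3·exp(γ·g)` or `k1` values put the 1 h step outside the RK4 stability
region — this is a real boundary of the method, and rejecting such sets is
intentional: they are also biologically implausible (sub-hour turnover).

Exponent arguments inside the kernel are capped at 40 (e^40 ≈ 2.4e17) so an
aggressive candidate produces a finite, penalised simulation rather than an
overflow.

Step-halving agreement (1 h vs 0.1 h, 1e-5 relative) is asserted after the
first simulated day: the observation-anchored initial state generally sits
off the fast starch-exchange manifold, and the resulting O(1/k)-hour
relaxation layer is a property of the initial condition, not of the smooth
solution either step size claims to track.

Initial conditions anchor to the first observation: `Csol`, `Csta` from the
mean observed SS/ST at the earliest sampled age, `Coth` as the remainder of
`c_DW·DW`; simulations start at that age (≈5 daa for the cherry-type, ≈9 daa
for the large-fruited genotype).

## Model inputs

Fresh and dry weight are Gompertz curves `W(t)=a·exp(−b·exp(−c·t))` fitted by
nonlinear least squares (hours since anthesis); `dDW/dt = c·W·log(a/W)` is
the analytic derivative and RGR its ratio to DW, clamped at 0.  Thermal time
accumulates hourly rectified temperature, `Σ max(T−5.7, 0)/24`.  Water
content is `100·(FW−DW)/FW`; its developmental upper boundary `WCmax(DD) =
p∞ − Δ·exp(−r·DD)` is fitted to the per-date maxima of the water-content
measurements pooled over treatments, and WC is capped at the boundary where
fitted curves cross (a cap beyond 2 percentage points triggers a warning).

## Empirical rate diagnostics

Inverting the starch and other-compound balances gives
`k1 = (dCoth/dt)/Csol` and `k3 = k2·Csta/Csol + (dCsta/dt)/Csol` directly
from observation-derived pools, with `k2` set to 0.5 h⁻¹ by convention at
this stage.  Pool derivatives come from a degree-2 local polynomial
regression with tricube weights (span 0.5 of the points, configurable); the
derivative is read off the smooth.  Ages with `Csol < 1e-6` g C are dropped.
The package regresses the empirical k1 on RGR per treatment; on synthetic
study data the R² values centre near 0.92.

## Calibration

The criterion is variance-weighted least squares on SS and ST (dry-weight
basis), summed over all data sets of a genotype, with one scalar variance
per variable — the sample variance of all replicate observations pooled over
the genotype (the criterion's weights carry no time index).  Search: a
real-coded genetic algorithm, population 100, elitist tournament selection,
blend crossover, Gaussian mutation with annealed step size, terminated when
the best criterion fails to improve for a fixed number of generations
(default 50; the improvement tolerance defaults to 1e-9 and the scaled
studies use a relative 1e-3 so the rule actually fires).  Repeated seeded
runs form a parameter ensemble (per-parameter SDs); the best restart can be
refined by a bounds-respecting Nelder-Mead simplex (derivative-free).
Default search box: λ∈[0,10], α∈[0,5], β∈[−1,1], k2∈[0,1], k30∈[0,5],
γ∈[−1,1], u∈[0,1500] dd, τ∈[1,500] dd.

Profile-likelihood 95% intervals scan each parameter from the optimum toward
each bound, re-optimising all other parameters (warm-started Nelder-Mead) at
each grid point; the interval collects values whose profiled criterion stays
within χ²₁(0.95)=3.84 of the minimum (the criterion treated as −2·log
likelihood up to a constant under Gaussian errors), endpoints refined by
bisection, bound-hitting sides flagged open-ended.

### Identifiability

At daily sampling the starch pool relaxes on a ~1/k2 (≈2–4 h) timescale, so
observations constrain essentially only the ratio k3/k2: the criterion
surface has a flat ridge along which k2 and k30 rise together.  λ and (when
the design contains water-content contrasts) γ are sharply identified; u is
moderately identified; k2 and k30 individually are not — their ensemble SDs
and profile intervals are wide by construction.  Parameter-recovery claims
in the tests reflect this: λ, u, γ recover to a few percent in the median,
k30 does not, and the corresponding assertion documents that limit.

## Model comparison and validation

Two-variable AIC: `AIC = log|M_k| + (2kq + q(1+q))/n` with `M_k` the
residual covariance about zero of (SS, ST), q=2, k=5 (plain) or 8
(water-content variant), natural logarithm, penalty divided by n so AIC
stays O(1).  Goodness of fit is RRMSE (RMSE/mean of observations) on all
four concentration variables; reported statistics average over the
calibration ensemble.  In the scaled model-selection study the AIC is scored
at each variant's best calibrated parameter set instead: averaging over an
ensemble only reflects model capacity once each run has converged, and at a
handful of restarts the larger variant's unconverged runs would contaminate
the average with optimiser noise.  Cross-validation holds out each treatment-year data
set in turn, recalibrates on the rest and reports RRMSEP on the held-out
set; prediction uses the best *feasible* training parameter set on the
held-out trajectory (a set outside the RK4 stability region there cannot
produce a prediction), and a fold with no feasible set reports NaN.

## Virtual experiment

Four scenarios perturb only the water content entering the rate laws — C
(control), WS (−δ percentage points throughout, δ=2 by default), CWS
(control early, stressed late) and WSC (the mirror) — with a step change at
the genotype's switch age (30 daa cherry-type, 45 daa large-fruited).  DW,
FW, temperature and thermal time are shared, so total carbon is identical
across scenarios (tested at integrator tolerance) and any pool difference is
pure repartitioning.  For concentrations the fresh weight in the denominator
is by default recomputed from the perturbed water content
(`FW = DW/(1−WC/100)`), so dilution/dehydration effects are visible; a flag
restores the shared base FW.

## Synthetic data generator

The generator emulates the study's structure, not its exact numbers: two
genotype templates (a ~8 g cherry-type with a 45-day season and a ~110 g
large-fruited type with a 60-day season) with Gompertz FW/DW truths, a
saturating water-content boundary sitting a small margin above the control
water content, and the published best-estimate parameter sets as generating
truth.  Five treatments perturb the weight asymptotes and water content the
way crop load and irrigation do (low load: larger, slightly drier fruit;
water deficit: smaller, drier fruit — strongly so only for the large-fruited
genotype, matching the observed genotype dependence).  The hourly climate is
a 20 °C mean with a 6 °C diurnal sine and AR(1) day-to-day noise (SD 1.5 °C,
lag-0.7).

Observation noise is multiplicative lognormal, CV 5% by default, with 3–5
replicate-like samples (default 4) per date.  FW and DW of one fruit share
the fruit-size error with a smaller independent residual on the dry-matter
ratio (both are measured on the same sampled fruit), so the derived water
content carries a realistically small error — important because the WCmax
boundary is fitted to per-date *maxima*, a statistic biased upward by noise.

What the generator does not emulate: between-fruit biological heterogeneity
beyond lognormal noise, truss-position and within-truss effects, missing
data, photo-derived versus destructive measurement mixtures, or any
systematic model misspecification.  Green tests on synthetic data therefore
show that the pipeline recovers a truth *of the model's own form* under
realistic noise and sampling — not that the model is correct for real fruit.

## Scale of the shipped studies

The pre-registered studies in `tomsugar.studies` (shared by the tests and
`scripts/acceptance.py`) run at a single-CPU scale chosen once: parameter
recovery uses 20 seeds × 10 GA restarts (population 100, stall 20,
generation cap 50, short simplex polish per restart) on the large-fruited
genotype with true input curves; model selection uses 10 seeds × 3 restarts
per variant on the cherry-type genotype through the full fitted pipeline;
cross-validation uses 3 restarts per fold; the conservation suite uses 50
random feasible configurations.  The reproduction script runs the same
studies with 10 recovery seeds.

## Known limitations

* k2/k30 are not separately identifiable from daily concentration data (see
  above); only their ratio is meaningful.
* The 1 h RK4 step bounds the admissible rate-constant magnitudes; stiff
  candidates are rejected rather than sub-stepped.
* The WCmax boundary inherits the upward bias of a max statistic under
  observation noise; with noisy inputs the water-content gap, and hence γ̂,
  is biased accordingly.
* Total soluble sugars are one pool: no sucrose/hexose split, no cellular
  compartmentation, no explicit respiration submodel.
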