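"""Parameter estimation for the fruit carbon-partitioning models.

Calibration minimises a variance-weighted least-squares criterion over the
soluble-sugar and starch concentrations on a dry-weight basis,

    criterion = sum (y_obs_SS - y_sim_SS)^2 / var_SS
              + sum (y_obs_ST - y_sim_ST)^2 / var_ST

summed over every data set (treatment x year) of a genotype, with one scalar
variance per variable pooled over the genotype's calibration data.  The
search uses a real-coded genetic algorithm (population 100, termination after
a fixed number of stalled generations), repeated from independent seeds to
form a parameter ensemble; per-parameter SDs over the ensemble and
profile-likelihood 95% confidence intervals of the best set quantify
identifiability.

Infeasible parameter sets (RK4 driven out of the non-negative region) receive
a large penalty rather than an exception, so the GA simply avoids them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .constants import C_SOL, C_STA
from .core import (
    FREE_PARAMS,
    PARAM_NAMES,
    FruitTrajectory,
    ModelParameters,
    Variant,
    initial_state,
    integrate_batch,
)

__all__ = [
    "ObservationSet",
    "CriterionObjective",
    "GAConfig",
    "GAResult",
    "CalibrationResult",
    "DEFAULT_BOUNDS",
    "PENALTY",
    "bounds_array",
    "ga_optimize",
    "calibrate_ensemble",
    "profile_likelihood_ci",
    "pooled_variances",
]

#: Criterion value assigned to infeasible simulations.
PENALTY = 1e12

#: Default search box per parameter; wide enough to contain published
#: estimates for both genotypes with large margins.
DEFAULT_BOUNDS = {
    "lam": (0.0, 10.0),
    "alpha": (0.0, 5.0),
    "beta": (-1.0, 1.0),
    "k2": (0.0, 1.0),
    "k30": (0.0, 5.0),
    "gamma": (-1.0, 1.0),
    "u": (0.0, 1500.0),
    "tau": (1.0, 500.0),
}


@dataclass
class ObservationSet:
    """Replicate-level sugar/starch observations of one data set.

    ``age_d`` in days after anthesis (one entry per replicate measurement);
    ``ss``/``st`` in g per 100 g DW; ``var_ss``/``var_st`` are the scalar
    variances used to weight the criterion.  Optional ``ssc``/``stc``
    (fresh-weight basis) support the four-variable goodness-of-fit report.
    """

    age_d: np.ndarray
    ss: np.ndarray
    st: np.ndarray
    var_ss: float
    var_st: float
    ssc: np.ndarray | None = None
    stc: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.age_d = np.asarray(self.age_d, dtype=float)
        self.ss = np.asarray(self.ss, dtype=float)
        self.st = np.asarray(self.st, dtype=float)
        if not (self.age_d.shape == self.ss.shape == self.st.shape):
            raise ValueError("age, SS and ST arrays must be aligned")
        if self.var_ss <= 0 or self.var_st <= 0:
            raise ValueError("variances must be positive")


def pooled_variances(datasets: list[ObservationSet]) -> tuple[float, float]:
    """Sample variances of SS and ST pooled over a genotype's data sets."""
    ss = np.concatenate([d.ss for d in datasets])
    st = np.concatenate([d.st for d in datasets])
    return float(np.var(ss, ddof=1)), float(np.var(st, ddof=1))


def _free_to_full(x: np.ndarray, variant: Variant) -> np.ndarray:
    """Expand free-parameter rows to the canonical 8-column matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    full = np.zeros((x.shape[0], 8))
    for j, name in enumerate(FREE_PARAMS[variant]):
        full[:, PARAM_NAMES.index(name)] = x[:, j]
    return full


class CriterionObjective:
    """Batched variance-weighted criterion over a genotype's data sets.

    Callable on a free-parameter vector (returns a float) or on a matrix of
    candidate rows (returns a vector) — the matrix form is what the genetic
    algorithm uses, one RK4 kernel call per data set per generation.
    """

    def __init__(
        self,
        datasets: list[tuple[ObservationSet, FruitTrajectory]],
        variant: Variant,
    ):
        self.variant = variant
        self.datasets = datasets
        self._prepared = []
        for obs, traj in datasets:
            ages = np.unique(obs.age_d)
            if ages[0] * 24.0 < traj.t[0] - 1e-9 or ages[-1] * 24.0 > traj.t[-1] + 1e-9:
                raise ValueError(
                    f"trajectory does not cover the observation ages of {obs.name!r}"
                )
            first = ages[0]
            sel = obs.age_d == first
            init = initial_state(
                float(obs.ss[sel].mean()),
                float(obs.st[sel].mean()),
                float(traj.interp("dw", first * 24.0)),
            )
            t_obs = obs.age_d * 24.0
            # linear-interpolation stencils into the trajectory grid
            pos = (t_obs - traj.t[0]) / traj.dt
            i0 = np.clip(np.floor(pos).astype(np.int64), 0, traj.t.size - 2)
            w = pos - i0
            dw_obs = traj.interp("dw", t_obs)
            self._prepared.append(
                {
                    "obs": obs,
                    "traj": traj,
                    "init": init.to_array(),
                    "i0": i0,
                    "w": w,
                    "dw": dw_obs,
                }
            )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        full = _free_to_full(x, self.variant)
        P = full.shape[0]
        crit = np.zeros(P)
        alive = np.ones(P, dtype=bool)
        for prep in self._prepared:
            obs = prep["obs"]
            states, ok = integrate_batch(prep["traj"], full, prep["init"])
            alive &= ok
            i0, w = prep["i0"], prep["w"]
            csol = states[:, i0, 0] * (1 - w) + states[:, i0 + 1, 0] * w
            csta = states[:, i0, 1] * (1 - w) + states[:, i0 + 1, 1] * w
            ss_sim = 100.0 * csol / (C_SOL * prep["dw"])
            st_sim = 100.0 * csta / (C_STA * prep["dw"])
            crit += ((obs.ss - ss_sim) ** 2).sum(axis=1) / obs.var_ss
            crit += ((obs.st - st_sim) ** 2).sum(axis=1) / obs.var_st
        crit = np.where(alive & np.isfinite(crit), crit, PENALTY)
        return float(crit[0]) if single else crit

    def params(self, x) -> ModelParameters:
        return ModelParameters.from_free(np.asarray(x, dtype=float), self.variant)


def bounds_array(
    variant: Variant, overrides: dict[str, tuple[float, float]] | None = None
) -> np.ndarray:
    """Search box for the free parameters of ``variant`` as a (k, 2) array."""
    table = dict(DEFAULT_BOUNDS)
    if overrides:
        table.update(overrides)
    out = np.array([table[name] for name in FREE_PARAMS[variant]], dtype=float)
    if np.any(out[:, 0] >= out[:, 1]):
        raise ValueError("each bound must satisfy lower < upper")
    return out


@dataclass
class GAConfig:
    """Real-coded genetic-algorithm settings.

    ``stall_generations`` is the termination rule: stop once the best
    criterion has not improved for that many consecutive generations.
    """

    population_size: int = 100
    stall_generations: int = 50
    max_generations: int = 500
    elite: int = 5
    tournament: int = 3
    crossover_prob: float = 0.9
    mutation_prob: float = 0.15
    mutation_sigma: float = 0.10
    mutation_decay: float = 0.97
    mutation_sigma_min: float = 0.003
    stall_tol: float = 1e-9


@dataclass
class GAResult:
    x: np.ndarray
    criterion: float
    n_generations: int
    seed: int | None = None


def ga_optimize(
    objective,
    bounds: np.ndarray,
    config: GAConfig | None = None,
    seed=0,
) -> GAResult:
    """Minimise a batched objective with a seeded real-coded GA.

    ``objective`` maps an (N, k) matrix to an (N,) criterion vector.  Elitist
    tournament selection, blend crossover and Gaussian mutation; fully
    reproducible for a given seed.
    """
    config = config or GAConfig()
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be a (k, 2) array with lower < upper")
    k = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(seed)
    P = config.population_size
    pop = lo + rng.random((P, k)) * span
    fit = np.asarray(objective(pop), dtype=float)
    order = np.argsort(fit)
    best_x = pop[order[0]].copy()
    best_f = float(fit[order[0]])
    stall = 0
    gen = 0
    for gen in range(1, config.max_generations + 1):
        # tournament selection of parents
        cand = rng.integers(0, P, size=(P, config.tournament))
        winners = cand[np.arange(P), np.argmin(fit[cand], axis=1)]
        parents = pop[winners]
        # blend crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, P - 1, 2):
            if rng.random() < config.crossover_prob:
                mix = rng.uniform(-0.25, 1.25, size=k)
                p1, p2 = parents[i], parents[i + 1]
                children[i] = mix * p1 + (1 - mix) * p2
                children[i + 1] = mix * p2 + (1 - mix) * p1
        # Gaussian mutation with annealed step size
        sigma = max(
            config.mutation_sigma * config.mutation_decay**gen,
            config.mutation_sigma_min,
        )
        mutate = rng.random((P, k)) < config.mutation_prob
        children = children + mutate * rng.normal(0.0, sigma, size=(P, k)) * span
        np.clip(children, lo, hi, out=children)
        # elitism: keep the current best rows
        elite_idx = np.argsort(fit)[: config.elite]
        children[: config.elite] = pop[elite_idx]
        pop = children
        fit = np.asarray(objective(pop), dtype=float)
        imin = int(np.argmin(fit))
        if fit[imin] < best_f - config.stall_tol * (1.0 + abs(best_f)):
            best_f = float(fit[imin])
            best_x = pop[imin].copy()
            stall = 0
        else:
            stall += 1
            if fit[imin] < best_f:
                best_f = float(fit[imin])
                best_x = pop[imin].copy()
        if stall >= config.stall_generations:
            break
    return GAResult(x=best_x, criterion=best_f, n_generations=gen)


@dataclass
class CalibrationResult:
    """Ensemble of repeated GA calibrations of one genotype and variant."""

    variant: Variant
    free_names: tuple[str, ...]
    ensemble: np.ndarray  # (n_repeats, k) free-parameter rows
    criteria: np.ndarray  # (n_repeats,)
    seeds: list
    feasible: np.ndarray  # bool mask; penalty-only runs are excluded from SDs

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.criteria))

    @property
    def best_free(self) -> np.ndarray:
        return self.ensemble[self.best_index]

    @property
    def best_criterion(self) -> float:
        return float(self.criteria[self.best_index])

    @property
    def best(self) -> ModelParameters:
        return ModelParameters.from_free(self.best_free, self.variant)

    @property
    def sd(self) -> np.ndarray | None:
        good = self.ensemble[self.feasible]
        if good.shape[0] < 2:
            return None
        return good.std(axis=0, ddof=1)

    def ensemble_params(self) -> list[ModelParameters]:
        return [
            ModelParameters.from_free(row, self.variant)
            for row in self.ensemble[self.feasible]
        ]


def polish(objective, x, bounds, maxfev: int = 4000):
    """Derivative-free simplex refinement of a candidate within the bounds."""
    res = minimize(
        lambda v: float(objective(v)),
        np.asarray(x, dtype=float),
        method="Nelder-Mead",
        bounds=[tuple(b) for b in np.asarray(bounds, dtype=float)],
        options={"maxfev": maxfev, "xatol": 1e-7, "fatol": 1e-9},
    )
    return res.x, float(res.fun)


def calibrate_ensemble(
    objective: CriterionObjective,
    bounds: np.ndarray,
    n_repeats: int = 100,
    base_seed: int = 0,
    config: GAConfig | None = None,
    polish_best: bool = False,
) -> CalibrationResult:
    """Repeat the GA search from independent seeds and collect the ensemble.

    With ``polish_best`` the best restart is refined by a derivative-free
    simplex search (the ensemble rows and SDs stay pure-GA).
    """
    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    rows, crits, seeds = [], [], []
    for i in range(n_repeats):
        seed = np.random.SeedSequence([int(base_seed), i])
        res = ga_optimize(objective, bounds, config=config, seed=seed)
        rows.append(res.x)
        crits.append(res.criterion)
        seeds.append((int(base_seed), i))
    if polish_best:
        ibest = int(np.argmin(crits))
        x_pol, f_pol = polish(objective, rows[ibest], bounds)
        if f_pol < crits[ibest]:
            rows[ibest], crits[ibest] = x_pol, f_pol
    crits = np.asarray(crits)
    return CalibrationResult(
        variant=objective.variant,
        free_names=FREE_PARAMS[objective.variant],
        ensemble=np.asarray(rows),
        criteria=crits,
        seeds=seeds,
        feasible=crits < PENALTY / 2,
    )


def _reoptimize(objective, x_start, fixed_idx, fixed_value, bounds):
    """Minimise over the non-fixed parameters with derivative-free Nelder-Mead."""
    k = len(x_start)
    free_idx = [j for j in range(k) if j != fixed_idx]
    if not free_idx:
        x = np.array(x_start, dtype=float)
        x[fixed_idx] = fixed_value
        return float(objective(x)), x

    def wrapped(sub):
        x = np.array(x_start, dtype=float)
        x[fixed_idx] = fixed_value
        x[free_idx] = sub
        return float(objective(x))

    sub0 = np.asarray(x_start, dtype=float)[free_idx]
    sub_bounds = [tuple(bounds[j]) for j in free_idx]
    res = minimize(
        wrapped,
        sub0,
        method="Nelder-Mead",
        bounds=sub_bounds,
        options={"xatol": 1e-6, "fatol": 1e-8, "maxfev": 4000},
    )
    x = np.array(x_start, dtype=float)
    x[fixed_idx] = fixed_value
    x[free_idx] = res.x
    return float(res.fun), x


def profile_likelihood_ci(
    objective,
    best_x: np.ndarray,
    bounds: np.ndarray,
    level: float = 0.95,
    n_grid: int = 8,
    n_bisect: int = 8,
):
    """Profile-likelihood confidence intervals around a fitted optimum.

    For each parameter, scan a grid from the best value toward each bound,
    re-optimising all other parameters at every grid point (the profiled
    criterion); the interval collects values whose profiled criterion stays
    within ``chi2_1(level)`` of the minimum, with endpoints refined by
    bisection.  An endpoint that reaches the search box is reported as
    open-ended on that side.

    Returns a list of dicts with ``low``, ``high``, ``open_low``,
    ``open_high`` per parameter.
    """
    best_x = np.asarray(best_x, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    f_best = float(objective(best_x))
    threshold = f_best + float(chi2.ppf(level, df=1))
    out = []
    for j in range(best_x.size):
        endpoints = {}
        for side, bound in (("low", bounds[j, 0]), ("high", bounds[j, 1])):
            if np.isclose(best_x[j], bound):
                endpoints[side] = (float(bound), True)
                continue
            grid = np.linspace(best_x[j], bound, n_grid + 1)[1:]
            x_warm = best_x
            inside_val = best_x[j]
            crossed = False
            for g in grid:
                f_prof, x_opt = _reoptimize(objective, x_warm, j, g, bounds)
                if f_prof <= threshold:
                    inside_val, x_warm = g, x_opt
                else:
                    lo_v, hi_v = inside_val, g
                    for _ in range(n_bisect):
                        mid = 0.5 * (lo_v + hi_v)
                        f_mid, x_mid = _reoptimize(objective, x_warm, j, mid, bounds)
                        if f_mid <= threshold:
                            lo_v, x_warm = mid, x_mid
                        else:
                            hi_v = mid
                    endpoints[side] = (float(0.5 * (lo_v + hi_v)), False)
                    crossed = True
                    break
            if not crossed:
                endpoints[side] = (float(bound), True)
        out.append(
            {
                "low": min(endpoints["low"][0], best_x[j]),
                "high": max(endpoints["high"][0], best_x[j]),
                "open_low": endpoints["low"][1],
                "open_high": endpoints["high"][1],
            }
        )
    return out
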