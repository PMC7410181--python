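"""Model comparison and validation: multivariate AIC, RRMSE, cross-validation.

Both model variants are compared on identical data with the two-variable
Akaike information criterion

    AIC = log|M_k| + (2*k*q + q*(1+q)) / n,      M_k = R R^T / n

where R stacks the residuals of the two calibrated variables (SS and ST on a
dry-weight basis, q = 2), k counts free parameters (5 without, 8 with the
water-content terms) and n is the number of observation pairs.  Goodness of
fit is the relative RMSE (RMSE divided by the observed mean) on all four
concentration variables.  Predictive quality comes from leave-one-
treatment-out cross-validation: recalibrate on four data sets, predict the
fifth, and report the relative RMSE of prediction (RRMSEP).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import C_SOL, C_STA
from .calibration import (
    CriterionObjective,
    GAConfig,
    ObservationSet,
    bounds_array,
    calibrate_ensemble,
)
from .core import (
    FREE_PARAMS,
    FruitTrajectory,
    IntegrationError,
    ModelParameters,
    Variant,
    initial_state,
    integrate,
)

__all__ = [
    "residual_covariance",
    "aic",
    "rrmse",
    "simulate_observations",
    "evaluate_fit",
    "cross_validate",
]


def residual_covariance(y_obs: np.ndarray, y_sim: np.ndarray) -> np.ndarray:
    """Residual covariance about zero, M_k = R R^T / n, for paired variables.

    ``y_obs`` and ``y_sim`` are (q, n) arrays (rows = variables).
    """
    y_obs = np.atleast_2d(np.asarray(y_obs, dtype=float))
    y_sim = np.atleast_2d(np.asarray(y_sim, dtype=float))
    if y_obs.shape != y_sim.shape:
        raise ValueError("observed and simulated arrays must be aligned")
    n = y_obs.shape[1]
    if n < 3:
        raise ValueError("need at least 3 observation pairs")
    resid = y_obs - y_sim
    return resid @ resid.T / n


def aic(m_k: np.ndarray, k: int, n: int, q: int = 2) -> float:
    """Multivariable AIC: log|M_k| + (2kq + q(1+q))/n (natural logarithm).

    Smaller is better; only differences on identical data are meaningful.
    """
    m_k = np.asarray(m_k, dtype=float)
    det = float(np.linalg.det(m_k))
    if det <= 0:
        raise ValueError(
            "singular residual covariance; AIC undefined (inspect residuals)"
        )
    return float(np.log(det) + (2.0 * k * q + q * (1.0 + q)) / n)


def rrmse(obs, sim) -> float:
    """Relative root mean squared error: RMSE / mean(obs)."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.size == 0 or obs.shape != sim.shape:
        raise ValueError("need aligned, non-empty series")
    m = obs.mean()
    if m == 0:
        raise ValueError("mean of observations is zero; RRMSE undefined")
    return float(np.sqrt(np.mean((obs - sim) ** 2)) / m)


def simulate_observations(
    obs: ObservationSet, traj: FruitTrajectory, params: ModelParameters
) -> dict[str, np.ndarray]:
    """Simulate the four concentration variables at the observation ages."""
    ages = np.unique(obs.age_d)
    first = ages[0]
    sel = obs.age_d == first
    init = initial_state(
        float(obs.ss[sel].mean()),
        float(obs.st[sel].mean()),
        float(traj.interp("dw", first * 24.0)),
    )
    sim = integrate(traj, params, init)
    t_obs = obs.age_d * 24.0
    csol = np.interp(t_obs, sim.t, sim.csol)
    csta = np.interp(t_obs, sim.t, sim.csta)
    dw = traj.interp("dw", t_obs)
    fw = traj.interp("fw", t_obs)
    return {
        "ss": 100.0 * csol / (C_SOL * dw),
        "st": 100.0 * csta / (C_STA * dw),
        "ssc": 100.0 * csol / (C_SOL * fw),
        "stc": 100.0 * csta / (C_STA * fw),
    }


def _fit_rows(obs, traj, params, k):
    sim = simulate_observations(obs, traj, params)
    m_k = residual_covariance(
        np.vstack([obs.ss, obs.st]), np.vstack([sim["ss"], sim["st"]])
    )
    row = {
        "rrmse_ss": rrmse(obs.ss, sim["ss"]),
        "rrmse_st": rrmse(obs.st, sim["st"]),
        "aic": aic(m_k, k=k, n=obs.ss.size),
        "n": obs.ss.size,
    }
    if obs.ssc is not None:
        row["rrmse_ssc"] = rrmse(obs.ssc, sim["ssc"])
        row["rrmse_stc"] = rrmse(obs.stc, sim["stc"])
    return row


def evaluate_fit(
    datasets: list[tuple[ObservationSet, FruitTrajectory]],
    param_sets: list[ModelParameters],
) -> pd.DataFrame:
    """Per-data-set RRMSE and AIC, averaged over a parameter ensemble.

    Mirrors the reporting convention of averaging the goodness-of-fit
    statistics over the repeated-calibration ensemble.  Returns one row per
    data set plus a ``mean`` row.
    """
    if not param_sets:
        raise ValueError("need at least one parameter set")
    k = len(FREE_PARAMS[param_sets[0].variant])
    rows = []
    for obs, traj in datasets:
        acc = []
        for params in param_sets:
            acc.append(_fit_rows(obs, traj, params, k))
        mean_row = {key: float(np.mean([r[key] for r in acc])) for key in acc[0]}
        mean_row["dataset"] = obs.name
        rows.append(mean_row)
    table = pd.DataFrame(rows).set_index("dataset")
    table.loc["mean"] = table.mean()
    return table


def cross_validate(
    datasets: list[tuple[ObservationSet, FruitTrajectory]],
    variant: Variant,
    bounds_overrides: dict | None = None,
    ga_config: GAConfig | None = None,
    n_repeats: int = 3,
    base_seed: int = 0,
    polish_best: bool = False,
) -> pd.DataFrame:
    """Leave-one-data-set-out cross-validation (RRMSEP per held-out set).

    Each fold recalibrates the model on the remaining data sets (best of
    ``n_repeats`` GA runs) and predicts the held-out one; the returned frame
    has RRMSEP for SS, ST and, when fresh-weight observations are present,
    SSC and STC, plus a ``mean`` row.
    """
    if len(datasets) < 2:
        raise ValueError("cross-validation needs at least two data sets")
    names = [obs.name for obs, _ in datasets]
    if len(set(names)) != len(names):
        raise ValueError("data sets must have unique names")
    bounds = bounds_array(variant, bounds_overrides)
    rows = []
    for fold, (held_obs, held_traj) in enumerate(datasets):
        train = [d for i, d in enumerate(datasets) if i != fold]
        objective = CriterionObjective(train, variant)
        result = calibrate_ensemble(
            objective,
            bounds,
            n_repeats=n_repeats,
            base_seed=int(base_seed) + fold,
            config=ga_config,
            polish_best=polish_best,
        )
        # predict with the best training parameter set that can actually be
        # simulated on the held-out trajectory (a set outside the RK4
        # stability region there cannot produce a prediction at all)
        sim = None
        for idx in np.argsort(result.criteria):
            if not result.feasible[idx]:
                continue
            candidate = ModelParameters.from_free(result.ensemble[idx], variant)
            try:
                sim = simulate_observations(held_obs, held_traj, candidate)
                break
            except IntegrationError:
                continue
        if sim is None:
            rows.append({"dataset": held_obs.name, "rrmsep_ss": np.nan,
                         "rrmsep_st": np.nan, "criterion": result.best_criterion})
            continue
        row = {
            "dataset": held_obs.name,
            "rrmsep_ss": rrmse(held_obs.ss, sim["ss"]),
            "rrmsep_st": rrmse(held_obs.st, sim["st"]),
            "criterion": result.best_criterion,
        }
        if held_obs.ssc is not None:
            row["rrmsep_ssc"] = rrmse(held_obs.ssc, sim["ssc"])
            row["rrmsep_stc"] = rrmse(held_obs.stc, sim["stc"])
        rows.append(row)
    table = pd.DataFrame(rows).set_index("dataset")
    table.loc["mean"] = table.mean()
    return table
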