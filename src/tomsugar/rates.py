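"""Empirical reconstruction of the rate constants k1(t) and k3(t).

Inverting the starch and other-compound balance equations gives the rate
constants directly from observation-derived carbon pools:

    k1(t) = (dCoth/dt) / Csol
    k3(t) = k2 * Csta / Csol + (dCsta/dt) / Csol

with k2 set to an arbitrary constant (0.5 h^-1 by convention) at this
diagnostic stage.  Pool derivatives are estimated from a local polynomial
regression (degree 2, tricube weights) of the pools against fruit age; the
derivative is read off the smooth, not from raw differences, which keeps the
ratios stable near maturity where Csol is large and the fluxes are tiny.

These diagnostics are what motivate modelling k1 as proportional to RGR (the
empirical k1 is near-linear in RGR, with treatment-dependent slopes) and k3
as a falling sigmoid of thermal time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import C_DW, C_SOL, C_STA
from .core import FruitTrajectory

__all__ = [
    "PoolSeries",
    "pools_from_observations",
    "local_regression_smooth",
    "smoothed_rate",
    "empirical_k1",
    "empirical_k3",
    "rate_diagnostics",
]

#: Below this soluble-sugar carbon (g C) the rate ratios are numerically
#: meaningless and the age is dropped from diagnostics.
CSOL_FLOOR = 1e-6


@dataclass
class PoolSeries:
    """Observation-derived carbon pools on the sampling-age grid.

    ``age_d`` in days after anthesis, ``dd`` in degree-days; pools in g C;
    smoothed derivatives in g C h^-1.
    """

    age_d: np.ndarray
    dd: np.ndarray
    csol: np.ndarray
    csta: np.ndarray
    coth: np.ndarray
    dcsta_dt: np.ndarray = None
    dcoth_dt: np.ndarray = None


def pools_from_observations(ss, st, dw):
    """Invert the concentration definitions: pools (g C) from SS, ST and DW.

    Exact inverse of the pool-to-concentration conversion; raises if the
    implied other-compound carbon would be negative (inconsistent data).
    """
    ss = np.asarray(ss, dtype=float)
    st = np.asarray(st, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if np.any(ss < 0) or np.any(st < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(dw <= 0):
        raise ValueError("DW must be positive")
    csol = ss * dw * C_SOL / 100.0
    csta = st * dw * C_STA / 100.0
    coth = C_DW * dw - csol - csta
    if np.any(coth < -1e-9):
        raise ValueError("sugar + starch carbon exceeds dry-mass carbon")
    return csol, csta, np.maximum(coth, 0.0)


def local_regression_smooth(
    x, y, span: float = 0.5, degree: int = 2, x_out=None
):
    """Locally weighted polynomial smooth and its derivative.

    At each output point the ``span`` fraction of nearest observations is fit
    with a weighted polynomial (tricube weights on scaled distance); returns
    ``(smooth, d_smooth/dx)`` evaluated at ``x_out`` (default: the data grid).
    Exact for polynomials up to ``degree`` within the window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < degree + 3:
        raise ValueError("too few points for local regression")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if x_out is None:
        x_out = x
    x_out = np.atleast_1d(np.asarray(x_out, dtype=float))
    k = max(int(np.ceil(span * x.size)), degree + 2)
    k = min(k, x.size)
    smooth = np.empty_like(x_out)
    deriv = np.empty_like(x_out)
    for i, x0 in enumerate(x_out):
        dist = np.abs(x - x0)
        idx = np.argsort(dist, kind="stable")[:k]
        h = dist[idx].max()
        if h == 0:
            h = 1.0
        w = (1 - np.minimum(dist[idx] / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-6)  # keep the window point at the edge usable
        dx = x[idx] - x0
        design = np.vander(dx, degree + 1, increasing=True)
        wm = np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(design * wm, y[idx] * wm[:, 0], rcond=None)
        smooth[i] = coef[0]
        deriv[i] = coef[1]
    return smooth, deriv


def smoothed_rate(age_d, pool, span: float = 0.5):
    """Pool change rate (g C h^-1) from a degree-2 local-regression smooth.

    ``age_d`` in days; the derivative of the smooth is converted from per-day
    to per-hour.
    """
    age_d = np.asarray(age_d, dtype=float)
    pool = np.asarray(pool, dtype=float)
    if age_d.size < 5:
        raise ValueError("need at least 5 points to estimate a smoothed rate")
    smooth, deriv_per_day = local_regression_smooth(age_d, pool, span=span)
    return smooth, deriv_per_day / 24.0


def empirical_k1(csol, dcoth_dt):
    """k1 (h^-1) from the other-compound balance: (dCoth/dt)/Csol."""
    csol = np.asarray(csol, dtype=float)
    if np.any(csol <= 0):
        raise ValueError("Csol must be positive")
    return np.asarray(dcoth_dt, dtype=float) / csol


def empirical_k3(csol, csta, dcsta_dt, k2_assumed: float = 0.5):
    """k3 (h^-1) from the starch balance: k2*Csta/Csol + (dCsta/dt)/Csol."""
    if k2_assumed < 0:
        raise ValueError("assumed k2 must be non-negative")
    csol = np.asarray(csol, dtype=float)
    if np.any(csol <= 0):
        raise ValueError("Csol must be positive")
    return (
        k2_assumed * np.asarray(csta, dtype=float) / csol
        + np.asarray(dcsta_dt, dtype=float) / csol
    )


def build_pool_series(
    age_d, ss_mean, st_mean, traj: FruitTrajectory, span: float = 0.5
) -> PoolSeries:
    """Observation-derived pools plus smoothed fluxes on the sampling grid.

    ``ss_mean``/``st_mean`` are per-age mean concentrations (g 100 g^-1 DW);
    DW and thermal time are read from the trajectory at the sampling ages.
    """
    age_d = np.asarray(age_d, dtype=float)
    t_h = age_d * 24.0
    dw = traj.interp("dw", t_h)
    csol, csta, coth = pools_from_observations(ss_mean, st_mean, dw)
    _, dcsta = smoothed_rate(age_d, csta, span=span)
    _, dcoth = smoothed_rate(age_d, coth, span=span)
    csol_s, _ = smoothed_rate(age_d, csol, span=span)
    return PoolSeries(
        age_d=age_d,
        dd=traj.interp("dd", t_h),
        csol=np.maximum(csol_s, 0.0),
        csta=csta,
        coth=coth,
        dcsta_dt=dcsta,
        dcoth_dt=dcoth,
    )


def rate_diagnostics(
    pool_series_by_treatment: dict[str, PoolSeries],
    trajectories: dict[str, FruitTrajectory],
    k2_assumed: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy empirical-rate table and per-treatment k1-vs-RGR regressions.

    Returns ``(table, regressions)``: the table has one row per treatment and
    sampling age with thermal time, temperature, RGR and the empirical k1 and
    k3; the regression frame has slope, intercept and R^2 of k1 on RGR per
    treatment.  Ages with Csol below the floor are dropped.
    """
    rows = []
    reg_rows = []
    for name, series in pool_series_by_treatment.items():
        traj = trajectories[name]
        t_h = series.age_d * 24.0
        rgr = traj.interp("rgr", t_h)
        temp = traj.interp("temp", t_h)
        keep = series.csol > CSOL_FLOOR
        k1 = empirical_k1(series.csol[keep], series.dcoth_dt[keep])
        k3 = empirical_k3(
            series.csol[keep], series.csta[keep], series.dcsta_dt[keep], k2_assumed
        )
        for j, idx in enumerate(np.flatnonzero(keep)):
            rows.append(
                {
                    "treatment": name,
                    "age_d": series.age_d[idx],
                    "dd": series.dd[idx],
                    "temp": temp[idx],
                    "rgr": rgr[idx],
                    "k1_emp": k1[j],
                    "k3_emp": k3[j],
                }
            )
        if k1.size >= 3:
            res = stats.linregress(rgr[keep], k1)
            reg_rows.append(
                {
                    "treatment": name,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r2": res.rvalue**2,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(reg_rows)
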