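"""Growth-curve inputs: Gompertz fits, thermal time, water content.

The fruit model takes DW(t), FW(t), dDW/dt, RGR, thermal time and the water
content and its developmental upper boundary as hourly inputs.  Fresh and dry
weight observations are fitted with the Gompertz function

    W(t) = a * exp(-b * exp(-c * t)),    dW/dt = c * W * log(a / W)

with t in hours since anthesis.  Thermal time accumulates hourly rectified
temperature above the 5.7 degC base.  The upper boundary of water content over
development (WCmax) is a saturating exponential fitted to the per-date maxima
of the pooled water-content measurements across treatments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import T_BASE
from .core import FruitTrajectory

__all__ = [
    "GompertzParameters",
    "WcBoundary",
    "GrowthFitError",
    "fit_gompertz",
    "gompertz_derivative",
    "degree_days",
    "water_content",
    "fit_wcmax",
    "build_trajectory",
]


class GrowthFitError(RuntimeError):
    """Non-convergent or degenerate growth-curve fit."""


@dataclass(frozen=True)
class GompertzParameters:
    """Gompertz curve W(t) = a*exp(-b*exp(-c*t)); a in g, c in h^-1."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.c <= 0:
            raise ValueError("Gompertz parameters must be positive")

    def weight(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(-self.b * np.exp(-self.c * t))

    def __call__(self, t):
        return self.weight(t)


def gompertz_derivative(params: GompertzParameters, t) -> np.ndarray:
    """Analytic growth rate dW/dt = c * W * log(a / W) (g h^-1)."""
    w = params.weight(t)
    return params.c * w * np.log(params.a / w)


def _gompertz(t, a, b, c):
    return a * np.exp(-b * np.exp(-c * t))


def fit_gompertz(times_h, weights_g) -> GompertzParameters:
    """Nonlinear least-squares Gompertz fit of weight observations.

    ``times_h`` in hours since anthesis.  Starting values: ``a`` 5% above the
    largest observation, ``c`` from a log-linearised slope, ``b`` anchored at
    the first observation.  Deterministic given the data.
    """
    t = np.asarray(times_h, dtype=float)
    w = np.asarray(weights_g, dtype=float)
    if t.size < 4 or np.unique(t).size < 4:
        raise GrowthFitError("need at least 4 distinct time points")
    if np.any(w <= 0):
        raise GrowthFitError("weights must be positive")
    if w.max() / w.min() < 1.05:
        raise GrowthFitError("no detectable growth in the observations")
    a0 = 1.05 * w.max()
    # log-linearise: log(-log(W/a0)) = log(b) - c*t  (only where W < a0)
    mask = w < a0 * 0.999
    z = np.log(-np.log(w[mask] / a0))
    slope, intercept = np.polyfit(t[mask], z, 1)
    c0 = max(-slope, 1e-6)
    b0 = max(np.exp(intercept), 1e-6)
    p0 = (a0, b0, c0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gompertz, t, w, p0=p0, maxfev=20000,
                bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
            )
    except (RuntimeError, ValueError) as exc:
        raise GrowthFitError(f"Gompertz fit did not converge: {exc}") from exc
    fitted = GompertzParameters(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]))
    rss = float(np.sum((fitted.weight(t) - w) ** 2))
    rss0 = float(np.sum((_gompertz(t, *p0) - w) ** 2))
    if rss > rss0 * (1 + 1e-9):
        raise GrowthFitError("optimiser worsened the initial guess")
    return fitted


def degree_days(temp_hourly, t_base: float = T_BASE) -> np.ndarray:
    """Cumulative degree-days from an hourly, gap-free temperature series.

    Each hour contributes max(T - t_base, 0)/24; the returned series is
    aligned with the input (element i = thermal time accrued through hour i)
    and is non-decreasing.
    """
    temp = np.asarray(temp_hourly, dtype=float)
    if temp.ndim != 1 or temp.size == 0:
        raise ValueError("need a one-dimensional hourly temperature series")
    if np.any(~np.isfinite(temp)):
        raise ValueError("temperature series contains gaps (non-finite values)")
    return np.cumsum(np.maximum(temp - t_base, 0.0) / 24.0)


def water_content(fw, dw):
    """Water content as a percentage of fresh mass: 100*(FW-DW)/FW."""
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    if np.any(dw <= 0):
        raise ValueError("DW must be positive")
    if np.any(dw > fw * (1 + 1e-9)):
        raise ValueError("DW cannot exceed FW")
    out = 100.0 * (fw - dw) / fw
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WcBoundary:
    """Upper boundary of water content: WCmax(DD) = p_inf - delta*exp(-r*DD).

    ``p_inf`` (%) is the asymptote, ``delta`` (%) the initial deficit and
    ``r`` (per degree-day) the saturation rate; non-decreasing in DD.
    """

    p_inf: float
    delta: float
    r: float

    def __post_init__(self):
        if self.p_inf > 100:
            raise ValueError("asymptote cannot exceed 100%")
        if self.delta < 0 or self.r < 0:
            raise ValueError("delta and r must be non-negative")

    def __call__(self, dd) -> np.ndarray:
        dd = np.asarray(dd, dtype=float)
        out = self.p_inf - self.delta * np.exp(-self.r * dd)
        return float(out) if out.ndim == 0 else out


def fit_wcmax(dd_dates, wc_obs_per_date) -> WcBoundary:
    """Fit the WCmax boundary to per-date maxima of pooled WC measurements.

    ``dd_dates``: thermal time of each sampling date; ``wc_obs_per_date``: a
    sequence (one entry per date) of WC observations pooled over treatments,
    or an array of already-reduced per-date values.
    """
    dd = np.asarray(dd_dates, dtype=float)
    maxima = np.array([np.max(np.asarray(v, dtype=float)) for v in wc_obs_per_date])
    if dd.size < 3:
        raise GrowthFitError("need at least 3 sampling dates")
    if np.ptp(maxima) < 1e-9:
        # flat maxima: degenerate but well-defined constant boundary
        return WcBoundary(p_inf=float(maxima[0]), delta=0.0, r=0.0)

    def model(x, p_inf, delta, r):
        return p_inf - delta * np.exp(-r * x)

    p0 = (
        min(float(maxima.max()) + 0.5, 100.0),
        float(max(np.ptp(maxima), 1.0)),
        1.0 / max(dd.max(), 1.0),
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, dd, maxima, p0=p0, maxfev=20000,
                bounds=([0.0, 0.0, 0.0], [100.0, 100.0, 1.0]),
            )
    except (RuntimeError, ValueError) as exc:
        raise GrowthFitError(f"WCmax boundary fit did not converge: {exc}") from exc
    return WcBoundary(p_inf=float(popt[0]), delta=float(popt[1]), r=float(popt[2]))


def build_trajectory(
    gompertz_dw: GompertzParameters,
    gompertz_fw: GompertzParameters,
    temp_hourly,
    wc_boundary: WcBoundary,
    t_start_h: float,
    t_end_h: float,
    dt: float = 1.0,
    cap_warn_threshold: float = 2.0,
) -> FruitTrajectory:
    """Assemble the hourly model-input trajectory from fitted curves.

    ``temp_hourly`` must cover hour 0 (anthesis) through ``t_end_h`` so that
    thermal time accumulates from anthesis even when the simulation window
    starts at the first sampled age.  WC is capped at the boundary where the
    fitted curves cross; a cap larger than ``cap_warn_threshold`` percentage
    points triggers a warning because it signals inconsistent fits.
    """
    temp = np.asarray(temp_hourly, dtype=float)
    if t_end_h > temp.size - 1 + 1e-9:
        raise ValueError("temperature series does not cover the simulation window")
    t = np.arange(t_start_h, t_end_h + dt / 2, dt)
    hours = np.arange(temp.size, dtype=float)
    dd_hourly = degree_days(temp)

    def inputs_at(tt):
        dw = gompertz_dw.weight(tt)
        fw = gompertz_fw.weight(tt)
        if np.any(dw > fw):
            raise ValueError("fitted DW curve exceeds the FW curve")
        ddw = gompertz_derivative(gompertz_dw, tt)
        rgr = np.maximum(ddw / dw, 0.0)
        dd = np.interp(tt, hours, dd_hourly)
        wc_raw = water_content(fw, dw)
        if np.any(wc_raw <= 0):
            raise ValueError("degenerate water content: DW curve equals FW curve")
        wcmax = np.minimum(wc_boundary(dd), 100.0)
        wc = np.minimum(wc_raw, wcmax)
        if np.any(wc_raw - wc > cap_warn_threshold):
            warnings.warn(
                "WC capped at the boundary by more than "
                f"{cap_warn_threshold} percentage points; check the WCmax fit",
                stacklevel=3,
            )
        return dw, fw, ddw, rgr, dd, wc, wcmax

    dw, fw, ddw, rgr, dd, wc, wcmax = inputs_at(t)
    t_mid = t[:-1] + dt / 2
    _, _, ddw_m, rgr_m, dd_m, wc_m, wcmax_m = inputs_at(t_mid)
    return FruitTrajectory(
        t=t, dw=dw, fw=fw, ddw_dt=ddw, rgr=rgr,
        temp=np.interp(t, hours, temp), dd=dd, wc=wc, wcmax=wcmax,
        ddw_dt_mid=ddw_m, rgr_mid=rgr_m, dd_mid=dd_m, wc_mid=wc_m, wcmax_mid=wcmax_m,
    )
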