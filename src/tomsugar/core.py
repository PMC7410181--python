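"""Three-pool carbon balance of a growing tomato fruit.

The fruit's carbon is split between soluble sugars (``Csol``), starch
(``Csta``) and everything else — cell walls, organic acids, proteins
(``Coth``), all in g C per fruit.  Phloem import is estimated from growth
(c_DW * dDW/dt) plus respiration, and respiration cancels algebraically, so
the state equations are

    dCsol/dt = c_DW * dDW/dt + k2 * Csta - (k1(t) + k3(t)) * Csol
    dCsta/dt = k3(t) * Csol - k2 * Csta
    dCoth/dt = k1(t) * Csol

with first-order rate constants k1 (sugars -> other compounds), k2 (starch ->
sugars, constant) and k3 (sugars -> starch).  Two variants describe k1 and k3:

* plain:            k1 = lambda * RGR,   k3 = k30 / (1 + exp((DD - u) / tau))
* water-content:    the k1 prefactor and exponent and the k3 numerator are
  each multiplied by exp(coef * (WCmax - WC)), so that a fruit drier than the
  developmental upper boundary of water content shifts carbon away from (or
  toward) sugars.

The system is integrated with fixed-step fourth-order Runge-Kutta; the three
derivatives sum identically to the supply, so total carbon tracks
c_DW * DW(t) to quadrature accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from . import _rk4
from .constants import C_DW, C_SOL, C_STA

__all__ = [
    "Variant",
    "ModelParameters",
    "CarbonState",
    "ConcentrationRecord",
    "FruitTrajectory",
    "SimulationResult",
    "IntegrationError",
    "PARAM_NAMES",
    "FREE_PARAMS",
    "rate_k1",
    "rate_k3",
    "ode_rhs",
    "initial_state",
    "integrate",
    "concentrations",
]

#: Canonical parameter ordering used by every array interface in the package.
PARAM_NAMES = ("lam", "alpha", "beta", "k2", "k30", "gamma", "u", "tau")


class Variant(str, Enum):
    """Model variant: without or with water-content modulation of k1 and k3."""

    SUGAR = "sugar"
    SUGAR_WC = "sugar_wc"


#: Free (calibrated) parameters per variant; the plain variant pins the three
#: water-content coefficients at zero.
FREE_PARAMS = {
    Variant.SUGAR: ("lam", "k2", "k30", "u", "tau"),
    Variant.SUGAR_WC: PARAM_NAMES,
}


class IntegrationError(RuntimeError):
    """A pool left the feasible region (negative/non-finite) during RK4."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate-law coefficients of one model variant.

    Units: ``k2`` and ``k30`` are h^-1, ``u`` and ``tau`` degree-days, the
    rest dimensionless.
    """

    lam: float
    k2: float
    k30: float
    u: float
    tau: float
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    variant: Variant = Variant.SUGAR_WC

    def __post_init__(self):
        if self.lam < 0 or self.k2 < 0 or self.k30 < 0:
            raise ValueError("lambda, k2 and k30 must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.variant is Variant.SUGAR and (
            self.alpha != 0.0 or self.beta != 0.0 or self.gamma != 0.0
        ):
            raise ValueError("plain variant requires alpha = beta = gamma = 0")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.lam, self.alpha, self.beta, self.k2, self.k30, self.gamma, self.u, self.tau]
        )

    @classmethod
    def from_array(cls, arr: Sequence[float], variant: Variant) -> "ModelParameters":
        lam, alpha, beta, k2, k30, gamma, u, tau = (float(v) for v in arr)
        return cls(
            lam=lam, alpha=alpha, beta=beta, k2=k2, k30=k30, gamma=gamma,
            u=u, tau=tau, variant=variant,
        )

    @classmethod
    def from_free(
        cls, values: Sequence[float], variant: Variant
    ) -> "ModelParameters":
        """Build from the free-parameter vector of ``variant`` (calibration order)."""
        kwargs = dict(zip(FREE_PARAMS[variant], (float(v) for v in values)))
        return cls(variant=variant, **kwargs)

    def free_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FREE_PARAMS[self.variant]])


@dataclass(frozen=True)
class CarbonState:
    """Carbon pools per fruit (g C)."""

    csol: float
    csta: float
    coth: float

    def __post_init__(self):
        if self.csol < 0 or self.csta < 0 or self.coth < 0:
            raise ValueError("carbon pools must be non-negative")

    @property
    def total(self) -> float:
        return self.csol + self.csta + self.coth

    def to_array(self) -> np.ndarray:
        return np.array([self.csol, self.csta, self.coth])


@dataclass(frozen=True)
class ConcentrationRecord:
    """Sugar/starch concentrations: SS, ST per 100 g DW; SSC, STC per 100 g FW."""

    ss: np.ndarray | float
    st: np.ndarray | float
    ssc: np.ndarray | float
    stc: np.ndarray | float


@dataclass
class FruitTrajectory:
    """Hourly model inputs over one fruit's growth window.

    ``t`` is hours since anthesis on a uniform grid; the ``*_mid`` arrays hold
    the inputs at the RK4 step midpoints (analytic when the trajectory comes
    from fitted curves, linear interpolation otherwise).  ``wc`` and ``wcmax``
    are percentages of fresh weight, ``dd`` cumulative degree-days.
    """

    t: np.ndarray
    dw: np.ndarray
    fw: np.ndarray
    ddw_dt: np.ndarray
    rgr: np.ndarray
    temp: np.ndarray
    dd: np.ndarray
    wc: np.ndarray
    wcmax: np.ndarray
    ddw_dt_mid: np.ndarray = None
    rgr_mid: np.ndarray = None
    dd_mid: np.ndarray = None
    wc_mid: np.ndarray = None
    wcmax_mid: np.ndarray = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        for name in ("dw", "fw", "ddw_dt", "rgr", "temp", "dd", "wc", "wcmax"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have the same length as t")
            setattr(self, name, arr)
        steps = np.diff(self.t)
        if n < 2 or steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("time grid must be uniform and strictly increasing")
        if self.ddw_dt_mid is None:
            for name in ("ddw_dt", "rgr", "dd", "wc", "wcmax"):
                arr = getattr(self, name)
                setattr(self, name + "_mid", 0.5 * (arr[:-1] + arr[1:]))
        self._validate()

    def _validate(self):
        if np.any(self.dw > self.fw * (1 + 1e-9)):
            raise ValueError("DW must not exceed FW")
        if np.any(self.wc < 0) or np.any(self.wc > self.wcmax + 1e-9):
            raise ValueError("require 0 <= WC <= WCmax")
        if np.any(self.wcmax > 100 + 1e-9):
            raise ValueError("WCmax cannot exceed 100%")
        if np.any(self.rgr < 0):
            raise ValueError("RGR must be clamped at zero")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def interp(self, name: str, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of one input at arbitrary times within the grid."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t[0] - 1e-9) or np.any(t > self.t[-1] + 1e-9):
            raise ValueError("time outside trajectory support")
        return np.interp(t, self.t, getattr(self, name))


@dataclass
class SimulationResult:
    """Pool time series from one integration (arrays aligned with ``t``)."""

    t: np.ndarray
    csol: np.ndarray
    csta: np.ndarray
    coth: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.csol + self.csta + self.coth

    def concentrations(self, traj: FruitTrajectory) -> ConcentrationRecord:
        return concentrations_arrays(self.csol, self.csta, traj.dw, traj.fw)


def _wc_gap(params: ModelParameters, wc, wcmax) -> np.ndarray:
    wc = np.asarray(wc, dtype=float)
    wcmax = np.asarray(wcmax, dtype=float)
    if np.any(wc > wcmax + 1e-9):
        raise ValueError("WC may not exceed WCmax")
    return np.maximum(wcmax - wc, 0.0)


def rate_k1(params: ModelParameters, rgr, wc=None, wcmax=None):
    """k1 (h^-1): carbon conversion rate from soluble sugars to other compounds.

    Plain variant: ``lambda * RGR``; water-content variant:
    ``lambda * exp(alpha*(WCmax-WC)) * RGR ** exp(beta*(WCmax-WC))``.
    """
    rgr = np.asarray(rgr, dtype=float)
    if np.any(rgr < 0):
        raise ValueError("RGR must be non-negative (clamp before calling)")
    if params.variant is Variant.SUGAR:
        return params.lam * rgr
    gap = _wc_gap(params, wc, wcmax)
    expo = np.exp(params.beta * gap)
    with np.errstate(divide="ignore"):
        out = params.lam * np.exp(params.alpha * gap) * rgr**expo
    return np.where(rgr > 0, out, 0.0) if out.ndim else (out if rgr > 0 else 0.0)


def rate_k3(params: ModelParameters, dd, wc=None, wcmax=None):
    """k3 (h^-1): carbon conversion rate from soluble sugars to starch.

    A falling sigmoid of thermal time with inflexion ``u`` and width ``tau``;
    the water-content variant multiplies the numerator by
    ``exp(gamma*(WCmax-WC))``.
    """
    dd = np.asarray(dd, dtype=float)
    numer = params.k30
    if params.variant is Variant.SUGAR_WC:
        numer = numer * np.exp(params.gamma * _wc_gap(params, wc, wcmax))
    with np.errstate(over="ignore"):
        return numer / (1.0 + np.exp((dd - params.u) / params.tau))


def ode_rhs(
    state: CarbonState | np.ndarray,
    t: float,
    traj: FruitTrajectory,
    params: ModelParameters,
) -> np.ndarray:
    """Pool derivatives (g C h^-1) at time ``t``; they sum to c_DW * dDW/dt."""
    x = state.to_array() if isinstance(state, CarbonState) else np.asarray(state, float)
    rgr = max(float(traj.interp("rgr", t)), 0.0)
    wc = float(traj.interp("wc", t))
    wcmax = float(traj.interp("wcmax", t))
    wc = min(wc, wcmax)
    k1 = float(rate_k1(params, rgr, wc, wcmax))
    k3 = float(rate_k3(params, float(traj.interp("dd", t)), wc, wcmax))
    supply = C_DW * float(traj.interp("ddw_dt", t))
    dsol = supply + params.k2 * x[1] - (k1 + k3) * x[0]
    dsta = k3 * x[0] - params.k2 * x[1]
    doth = k1 * x[0]
    return np.array([dsol, dsta, doth])


def initial_state(ss: float, st: float, dw: float) -> CarbonState:
    """Carbon pools implied by observed concentrations at the start age.

    ``ss`` and ``st`` in g per 100 g DW, ``dw`` in g.  The remaining carbon
    (c_DW*DW minus sugar and starch carbon) is assigned to other compounds.
    """
    if dw <= 0:
        raise ValueError("DW must be positive")
    if ss < 0 or st < 0:
        raise ValueError("concentrations must be non-negative")
    csol = ss * dw * C_SOL / 100.0
    csta = st * dw * C_STA / 100.0
    coth = C_DW * dw - csol - csta
    if coth < -1e-12:
        raise ValueError(
            "observed sugar + starch carbon exceeds total dry-mass carbon"
        )
    return CarbonState(csol=csol, csta=csta, coth=max(coth, 0.0))


def _kernel_inputs(traj: FruitTrajectory):
    supply = C_DW * traj.ddw_dt
    supply_mid = C_DW * traj.ddw_dt_mid
    gap = np.maximum(traj.wcmax - traj.wc, 0.0)
    gap_mid = np.maximum(traj.wcmax_mid - traj.wc_mid, 0.0)
    with np.errstate(divide="ignore"):
        # log(0) = -inf encodes RGR = 0, collapsing k1 to zero in the kernel
        lrgr = np.log(np.maximum(traj.rgr, 0.0))
        lrgr_mid = np.log(np.maximum(traj.rgr_mid, 0.0))
    return (
        traj.dt,
        np.ascontiguousarray(supply),
        np.ascontiguousarray(supply_mid),
        np.ascontiguousarray(gap),
        np.ascontiguousarray(gap_mid),
        np.ascontiguousarray(lrgr),
        np.ascontiguousarray(lrgr_mid),
        np.ascontiguousarray(traj.dd),
        np.ascontiguousarray(traj.dd_mid),
    )


def integrate_batch(
    traj: FruitTrajectory,
    param_matrix: np.ndarray,
    init: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4-integrate ``P`` parameter rows on one trajectory.

    Rows follow :data:`PARAM_NAMES`; the water-free variant is encoded by
    zeros in the alpha/beta/gamma columns.  Returns ``(states, ok)`` with
    ``states`` of shape (P, T, 3); rows with ``ok`` false hit a negative or
    non-finite pool (infeasible parameters).
    """
    param_matrix = np.ascontiguousarray(param_matrix, dtype=float)
    init = np.ascontiguousarray(init, dtype=float)
    if init.ndim == 1:
        init = np.broadcast_to(init, (param_matrix.shape[0], 3)).copy()
    scale = max(1e-3, float(C_DW * traj.dw.max()))
    neg_floor = -1e-9 * scale
    return _rk4.rk4_batch(
        *_kernel_inputs(traj),
        param_matrix,
        init,
        neg_floor,
    )


def integrate(
    traj: FruitTrajectory,
    params: ModelParameters,
    init: CarbonState,
) -> SimulationResult:
    """Integrate the carbon balance over the trajectory support (fixed-step RK4).

    Raises :class:`IntegrationError` if a pool is driven below the negativity
    tolerance — infeasible parameter sets are reported, never silently clipped.
    """
    states, ok = integrate_batch(
        traj,
        params.to_array()[None, :],
        init.to_array(),
    )
    if not ok[0]:
        raise IntegrationError(
            "carbon pool became negative or non-finite during integration; "
            "the parameter set is infeasible at this step size"
        )
    return SimulationResult(
        t=traj.t.copy(),
        csol=states[0, :, 0],
        csta=states[0, :, 1],
        coth=states[0, :, 2],
    )


def concentrations_arrays(csol, csta, dw, fw) -> ConcentrationRecord:
    csol = np.asarray(csol, float)
    csta = np.asarray(csta, float)
    dw = np.asarray(dw, float)
    fw = np.asarray(fw, float)
    if np.any(dw <= 0):
        raise ValueError("DW must be positive")
    if np.any(fw < dw * (1 - 1e-9)):
        raise ValueError("FW must be at least DW")
    return ConcentrationRecord(
        ss=100.0 * csol / (C_SOL * dw),
        st=100.0 * csta / (C_STA * dw),
        ssc=100.0 * csol / (C_SOL * fw),
        stc=100.0 * csta / (C_STA * fw),
    )


def concentrations(state: CarbonState, dw: float, fw: float) -> ConcentrationRecord:
    """Convert carbon pools (g C) to the four concentration variables."""
    rec = concentrations_arrays(state.csol, state.csta, dw, fw)
    return ConcentrationRecord(
        ss=float(rec.ss), st=float(rec.st), ssc=float(rec.ssc), stc=float(rec.stc)
    )
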