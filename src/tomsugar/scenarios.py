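"""Virtual water-content experiment: C / WS / CWS / WSC scenarios.

The water content entering the rate laws is perturbed while dry weight,
fresh-weight growth, temperature and thermal time stay fixed, so any change
in the carbon pools is attributable to the water-content modulation of
metabolism alone:

* ``C``   - control, the unmodified water-content trajectory;
* ``WS``  - water content lowered by ``delta`` percentage points throughout;
* ``CWS`` - control early, stressed after the switch age (late stress);
* ``WSC`` - stressed early, control after the switch age (early stress).

Because total carbon is fixed by the shared growth curve, the scenarios can
only repartition carbon; concentration differences additionally reflect
dilution/dehydration when the fresh weight used in the concentration
denominator is recomputed from the perturbed water content
(FW = DW / (1 - WC/100), the default).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .constants import C_SOL, C_STA
from .core import (
    CarbonState,
    FruitTrajectory,
    ModelParameters,
    Variant,
    IntegrationError,
    integrate,
)

__all__ = ["ScenarioSet", "ScenarioRuns", "build_scenarios", "run_scenarios"]

SCENARIO_NAMES = ("C", "WS", "CWS", "WSC")


@dataclass
class ScenarioSet:
    """Four trajectories differing only in the water-content input."""

    base: FruitTrajectory
    delta: float
    switch_age_d: float
    trajectories: dict[str, FruitTrajectory]


def _shift_wc(traj: FruitTrajectory, shift: np.ndarray, shift_mid: np.ndarray):
    new = copy.deepcopy(traj)
    new.wc = traj.wc - shift
    new.wc_mid = traj.wc_mid - shift_mid
    if np.any(new.wc <= 0):
        raise ValueError("delta drives the water content to zero or below")
    return new


def build_scenarios(
    traj: FruitTrajectory, delta: float = 2.0, switch_age_d: float | None = None
) -> ScenarioSet:
    """Derive the four scenario trajectories from a control trajectory.

    ``delta`` is in percentage points of water content; ``switch_age_d`` (days
    after anthesis) splits the early window from the late window (e.g. 30 for
    a cherry-type fruit simulated to 45 daa, 45 for a large-fruited one
    simulated to 60 daa).  The perturbation is a step change at the switch.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if switch_age_d is None:
        switch_age_d = traj.t[-1] / 24.0 * 2.0 / 3.0
    switch_h = switch_age_d * 24.0
    if not (traj.t[0] < switch_h < traj.t[-1]):
        raise ValueError("switch age must fall inside the simulation window")
    ones = np.full(traj.t.size, delta)
    ones_mid = np.full(traj.t.size - 1, delta)
    late = (traj.t > switch_h).astype(float) * delta
    t_mid = traj.t[:-1] + traj.dt / 2
    late_mid = (t_mid > switch_h).astype(float) * delta
    early = delta - late
    early_mid = delta - late_mid
    trajectories = {
        "C": copy.deepcopy(traj),
        "WS": _shift_wc(traj, ones, ones_mid),
        "CWS": _shift_wc(traj, late, late_mid),
        "WSC": _shift_wc(traj, early, early_mid),
    }
    return ScenarioSet(
        base=traj, delta=delta, switch_age_d=switch_age_d, trajectories=trajectories
    )


@dataclass
class ScenarioRuns:
    """Per-scenario ensemble simulations: arrays of shape (n_params, T)."""

    t: np.ndarray
    csol: dict[str, np.ndarray]
    csta: dict[str, np.ndarray]
    coth: dict[str, np.ndarray]
    ssc: dict[str, np.ndarray]
    stc: dict[str, np.ndarray]
    skipped: dict[str, list[int]]


def run_scenarios(
    scenarios: ScenarioSet,
    ensemble: list[ModelParameters],
    init: CarbonState,
    concentration_fw: str = "recomputed",
) -> ScenarioRuns:
    """Simulate every scenario under every parameter set of the ensemble.

    ``concentration_fw`` selects the fresh weight used in the SSC/STC
    denominators: ``"recomputed"`` derives it from the perturbed water content
    and the shared dry weight (so dilution/dehydration effects show up in the
    concentrations), ``"base"`` keeps the control fresh weight.  Parameter
    sets that are infeasible for a scenario are recorded in ``skipped``.
    """
    if concentration_fw not in ("recomputed", "base"):
        raise ValueError("concentration_fw must be 'recomputed' or 'base'")
    for p in ensemble:
        if p.variant is not Variant.SUGAR_WC:
            # without water-content terms the scenarios are indistinguishable
            raise ValueError(
                "scenario runs require the water-content variant; the plain "
                "variant is insensitive to the perturbation by construction"
            )
    out = ScenarioRuns(
        t=scenarios.base.t.copy(),
        csol={}, csta={}, coth={}, ssc={}, stc={}, skipped={},
    )
    for name, traj in scenarios.trajectories.items():
        sols, stas, oths, sscs, stcs = [], [], [], [], []
        skipped = []
        if concentration_fw == "recomputed":
            fw = traj.dw / (1.0 - traj.wc / 100.0)
        else:
            fw = scenarios.base.fw
        for i, params in enumerate(ensemble):
            try:
                sim = integrate(traj, params, init)
            except IntegrationError:
                skipped.append(i)
                continue
            sols.append(sim.csol)
            stas.append(sim.csta)
            oths.append(sim.coth)
            sscs.append(100.0 * sim.csol / (C_SOL * fw))
            stcs.append(100.0 * sim.csta / (C_STA * fw))
        out.csol[name] = np.asarray(sols)
        out.csta[name] = np.asarray(stas)
        out.coth[name] = np.asarray(oths)
        out.ssc[name] = np.asarray(sscs)
        out.stc[name] = np.asarray(stcs)
        out.skipped[name] = skipped
    return out
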