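import numpy as np
import pytest

from tomsugar import synth


@pytest.fixture(scope="session")
def temp_series():
    """Deterministic hourly temperature covering the longest season."""
    return synth.generate_temperature(synth.ClimateConfig(), seed=123)


@pytest.fixture(scope="session")
def cherry_traj(temp_series):
    return synth.true_trajectory(synth.cherry_template(), temp_series)


@pytest.fixture(scope="session")
def large_traj(temp_series):
    return synth.true_trajectory(synth.large_template(), temp_series)


@pytest.fixture(scope="session")
def small_study():
    """One full synthetic study shared by pipeline-level tests."""
    return synth.generate_study(seed=3)


@pytest.fixture(scope="session")
def noiseless_study():
    import dataclasses

    cfg = dataclasses.replace(synth.default_config(), cv=0.0)
    return synth.generate_study(cfg, seed=3)


def constant_trajectory(
    n_hours=200,
    supply=0.004,
    rgr=0.005,
    dd=300.0,
    gap=0.0,
    dw=2.0,
    fw=30.0,
):
    """Hand-built trajectory with constant inputs (constant-coefficient ODE).

    The fields are deliberately mutually inconsistent (constant RGR with
    constant dDW/dt) — the integrator only reads the individual inputs, which
    is exactly what the closed-form oracle needs.
    """
    from tomsugar.core import FruitTrajectory
    from tomsugar.constants import C_DW

    t = np.arange(n_hours, dtype=float)
    ddw_dt = np.full(n_hours, supply / C_DW)
    wcmax = np.full(n_hours, 95.0)
    return FruitTrajectory(
        t=t,
        dw=np.full(n_hours, dw) + (supply / C_DW) * t,
        fw=np.full(n_hours, fw),
        ddw_dt=ddw_dt,
        rgr=np.full(n_hours, rgr),
        temp=np.full(n_hours, 20.0),
        dd=np.full(n_hours, dd),
        wc=wcmax - gap,
        wcmax=wcmax,
    )
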