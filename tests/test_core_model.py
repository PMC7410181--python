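"""Unit tests of the carbon-balance ODE system and its rate laws."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from tomsugar import (
    CarbonState,
    IntegrationError,
    ModelParameters,
    Variant,
    concentrations,
    initial_state,
    integrate,
    ode_rhs,
    rate_k1,
    rate_k3,
)
from tomsugar.constants import C_DW, C_SOL, C_STA
from tomsugar import synth

from conftest import constant_trajectory


CHERRY = synth.CHERRY_TRUE
LARGE = synth.LARGE_TRUE


class TestRateK1:
    def test_wc_variant_collapses_at_boundary(self):
        """At WC = WCmax both water-content exponentials are 1."""
        p = ModelParameters(lam=3.0, k2=0.4, k30=1.0, u=400, tau=50,
                            alpha=1.2, beta=0.3, gamma=0.1)
        assert rate_k1(p, 0.01, 90.0, 90.0) == pytest.approx(3.0 * 0.01, rel=1e-12)

    def test_zero_growth_gives_zero_rate(self):
        plain = ModelParameters(lam=2.0, k2=0.4, k30=1.0, u=400, tau=50,
                                variant=Variant.SUGAR)
        wc = ModelParameters(lam=2.0, k2=0.4, k30=1.0, u=400, tau=50,
                             alpha=1.0, beta=0.2, gamma=0.0)
        assert rate_k1(plain, 0.0) == 0.0
        assert rate_k1(wc, 0.0, 88.0, 92.0) == 0.0

    def test_cherry_values_match_direct_formula_evaluation(self):
        # independent arithmetic evaluation of the water-modulated rate law
        lam, alpha, beta = 4.324, 1.620, 0.187
        gap, rgr = 2.0, 0.01
        expected = lam * math.exp(alpha * gap) * rgr ** math.exp(beta * gap)
        p = ModelParameters(lam=lam, alpha=alpha, beta=beta, k2=CHERRY.k2,
                            k30=CHERRY.k30, gamma=CHERRY.gamma, u=CHERRY.u,
                            tau=CHERRY.tau)
        assert rate_k1(p, rgr, 90.0, 92.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_rgr_and_wc_above_boundary_rejected(self):
        p = CHERRY
        with pytest.raises(ValueError):
            rate_k1(p, -0.01, 90.0, 92.0)
        with pytest.raises(ValueError):
            rate_k1(p, 0.01, 93.0, 92.0)


class TestRateK3:
    def test_sigmoid_inflexion_is_half_maximum(self):
        p = ModelParameters(lam=1.0, k2=0.4, k30=0.8, u=400, tau=60,
                            alpha=0.0, beta=0.0, gamma=0.5)
        assert rate_k3(p, 400.0, 92.0, 92.0) == pytest.approx(0.4, rel=1e-12)

    def test_sigmoid_tail_vanishes(self):
        p = ModelParameters(lam=1.0, k2=0.4, k30=0.8, u=400, tau=60,
                            variant=Variant.SUGAR)
        assert rate_k3(p, 400.0 + 15 * 60.0) < 1e-4 * p.k30

    def test_large_fruit_values_match_direct_formula_evaluation(self):
        k30, gamma, u, tau = 0.125, 0.517, 413.02, 225.73
        dd, gap = 300.0, 2.0
        expected = k30 * math.exp(gamma * gap) / (1 + math.exp((dd - u) / tau))
        p = ModelParameters(lam=LARGE.lam, alpha=LARGE.alpha, beta=LARGE.beta,
                            k2=LARGE.k2, k30=k30, gamma=gamma, u=u, tau=tau)
        assert rate_k3(p, dd, 90.0, 92.0) == pytest.approx(expected, rel=1e-12)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(lam=1.0, k2=0.4, k30=0.8, u=400, tau=0.0)


class TestOdeRhs:
    def test_supply_only(self):
        traj = constant_trajectory(supply=C_DW * 0.01, rgr=0.0, dd=5000.0)
        p = ModelParameters(lam=1.0, k2=0.0, k30=0.5, u=100.0, tau=10.0,
                            variant=Variant.SUGAR)
        # k3 is dead far past the sigmoid, RGR=0 kills k1, k2=0
        d = ode_rhs(CarbonState(1.0, 0.5, 0.3), 50.0, traj, p)
        assert d == pytest.approx([C_DW * 0.01, 0.0, 0.0], abs=1e-12)

    def test_pure_starch_degradation_conserves_carbon(self):
        traj = constant_trajectory(supply=0.0, rgr=0.0, dd=5000.0)
        p = ModelParameters(lam=1.0, k2=0.1, k30=0.5, u=100.0, tau=10.0,
                            variant=Variant.SUGAR)
        d = ode_rhs(CarbonState(1.0, 0.5, 0.0), 50.0, traj, p)
        assert d == pytest.approx([0.05, -0.05, 0.0], abs=1e-12)

    def test_derivatives_sum_to_supply(self, cherry_traj):
        state = CarbonState(0.05, 0.03, 0.1)
        for t in (150.0, 400.0, 900.0):
            d = ode_rhs(state, t, cherry_traj, CHERRY)
            supply = C_DW * cherry_traj.interp("ddw_dt", t)
            assert d.sum() == pytest.approx(supply, rel=1e-12)


class TestInitialState:
    def test_direct_arithmetic(self):
        s = initial_state(25.0, 25.0, 1.0)
        assert s.csol == pytest.approx(0.1)
        assert s.csta == pytest.approx(0.111)
        assert s.coth == pytest.approx(0.44 - 0.1 - 0.111)

    def test_all_structural(self):
        s = initial_state(0.0, 0.0, 2.0)
        assert (s.csol, s.csta, s.coth) == (0.0, 0.0, pytest.approx(0.88))

    def test_infeasible_composition_rejected(self):
        with pytest.raises(ValueError):
            initial_state(80.0, 40.0, 1.0)


class TestIntegrate:
    def test_zero_rates_reduce_to_quadrature_of_supply(self, cherry_traj):
        p = ModelParameters(lam=0.0, k2=0.0, k30=0.0, u=100.0, tau=10.0,
                            variant=Variant.SUGAR)
        init = CarbonState(0.01, 0.005, 0.02)
        sim = integrate(cherry_traj, p, init)
        expected = init.csol + C_DW * (cherry_traj.dw - cherry_traj.dw[0])
        assert np.allclose(sim.csol, expected, rtol=1e-9)
        assert np.allclose(sim.csta, init.csta)
        assert np.allclose(sim.coth, init.coth)

    def test_constant_coefficients_match_matrix_exponential(self):
        """Closed form of the constant-coefficient linear system as oracle."""
        k1, k2, k3, supply = 0.03, 0.2, 0.08, 0.004
        rgr = 0.005
        traj = constant_trajectory(supply=supply, rgr=rgr, dd=300.0, gap=0.0)
        p = ModelParameters(lam=k1 / rgr, k2=k2, k30=k3 * (1 + math.exp((300 - 400) / 50.0)),
                            u=400.0, tau=50.0, variant=Variant.SUGAR)
        x0 = np.array([0.05, 0.02, 0.1])
        sim = integrate(traj, p, CarbonState(*x0))
        A = np.array([
            [-(k1 + k3), k2, 0.0],
            [k3, -k2, 0.0],
            [k1, 0.0, 0.0],
        ])
        # augmented system for the constant forcing term
        M = np.zeros((4, 4))
        M[:3, :3] = A
        M[0, 3] = supply
        for t in (50.0, 199.0):
            phi = expm(M * t)
            exact = phi[:3, :3] @ x0 + phi[:3, 3]
            idx = int(t)
            got = np.array([sim.csol[idx], sim.csta[idx], sim.coth[idx]])
            assert np.allclose(got, exact, rtol=1e-6, atol=1e-12)

    def test_step_halving_agreement(self, temp_series):
        """RK4 at 1 h agrees with RK4 at 0.1 h to 1e-5 relative.

        The first simulated day is excluded: the observation-anchored initial
        state sits off the fast starch-exchange manifold, and the resulting
        O(1/k) relaxation layer is not a statement about the smooth solution.
        """
        template = synth.cherry_template()
        coarse = synth.true_trajectory(template, temp_series, dt=1.0)
        fine = synth.true_trajectory(template, temp_series, dt=0.1)
        init = initial_state(template.init_ss, template.init_st, float(coarse.dw[0]))
        sim1 = integrate(coarse, template.true_params, init)
        sim2 = integrate(fine, template.true_params, init)
        idx = np.round((coarse.t - fine.t[0]) / 0.1).astype(int)
        scale = np.maximum(sim1.total, 1e-12)
        for a, b in ((sim1.csol, sim2.csol), (sim1.csta, sim2.csta),
                     (sim1.coth, sim2.coth)):
            assert np.max((np.abs(a - b[idx]) / scale)[24:]) < 1e-5

    def test_carbon_conservation_on_template_trajectories(self, cherry_traj, large_traj):
        for traj, params, (ss0, st0) in (
            (cherry_traj, CHERRY, (10.0, 12.0)),
            (large_traj, LARGE, (18.0, 10.0)),
        ):
            init = initial_state(ss0, st0, float(traj.dw[0]))
            sim = integrate(traj, params, init)
            target = C_DW * traj.dw
            assert np.max(np.abs(sim.total - target) / target) < 1e-6

    def test_infeasible_parameters_raise_not_clip(self, large_traj):
        # gamma * gap makes k3 enormous -> outside the RK4 stability region
        p = ModelParameters(lam=1.0, k2=0.9, k30=5.0, u=2000.0, tau=10.0,
                            alpha=0.0, beta=0.0, gamma=5.0)
        init = initial_state(18.0, 10.0, float(large_traj.dw[0]))
        with pytest.raises(IntegrationError):
            integrate(large_traj, p, init)

    def test_degenerate_wc_variant_identical_to_plain(self, cherry_traj):
        """alpha=beta=gamma=0 reproduces the plain variant bit for bit."""
        shared = dict(lam=2.0, k2=0.3, k30=0.6, u=450.0, tau=60.0)
        plain = ModelParameters(variant=Variant.SUGAR, **shared)
        degenerate = ModelParameters(variant=Variant.SUGAR_WC, alpha=0.0,
                                     beta=0.0, gamma=0.0, **shared)
        init = initial_state(10.0, 12.0, float(cherry_traj.dw[0]))
        sim_a = integrate(cherry_traj, plain, init)
        sim_b = integrate(cherry_traj, degenerate, init)
        assert np.array_equal(sim_a.csol, sim_b.csol)
        assert np.array_equal(sim_a.csta, sim_b.csta)
        assert np.array_equal(sim_a.coth, sim_b.coth)


class TestConcentrations:
    def test_dw_basis_arithmetic(self):
        rec = concentrations(CarbonState(0.4, 0.0, 0.1), dw=2.0, fw=20.0)
        assert rec.ss == pytest.approx(50.0)
        assert rec.st == 0.0
        assert rec.stc == 0.0

    def test_fw_dw_consistency(self):
        rec = concentrations(CarbonState(0.12, 0.05, 0.2), dw=1.5, fw=12.0)
        assert rec.ssc * 12.0 == pytest.approx(rec.ss * 1.5, rel=1e-12)
        assert rec.stc * 12.0 == pytest.approx(rec.st * 1.5, rel=1e-12)

    def test_invalid_dw_rejected(self):
        with pytest.raises(ValueError):
            concentrations(CarbonState(0.1, 0.1, 0.1), dw=0.0, fw=1.0)
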