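"""Tests of the criterion, the genetic algorithm and profile-likelihood CIs."""

import dataclasses

import numpy as np
import pytest

from tomsugar import synth
from tomsugar.calibration import (
    CalibrationResult,
    CriterionObjective,
    GAConfig,
    ObservationSet,
    bounds_array,
    calibrate_ensemble,
    ga_optimize,
    polish,
    pooled_variances,
    profile_likelihood_ci,
)
from tomsugar.core import FREE_PARAMS, Variant


@pytest.fixture(scope="module")
def noiseless_cherry():
    """Noiseless cherry study generated by the plain (5-parameter) variant."""
    plain_truth = dataclasses.replace(
        synth.CHERRY_TRUE, alpha=0.0, beta=0.0, gamma=0.0, variant=Variant.SUGAR
    )
    template = dataclasses.replace(synth.cherry_template(), true_params=plain_truth)
    cfg = dataclasses.replace(
        synth.default_config(), cv=0.0, genotypes=(template,)
    )
    study = synth.generate_study(cfg, seed=5)
    datasets, _ = synth.assemble_datasets(study, "cherry", use_fitted_growth=False)
    return study, datasets


class TestObjective:
    def test_perfect_fit_is_zero(self, noiseless_cherry):
        study, datasets = noiseless_cherry
        objective = CriterionObjective(datasets, Variant.SUGAR)
        truth = study.genotypes["cherry"].template.true_params
        assert objective(truth.free_array()) < 1e-12

    def test_hand_summed_residuals(self, noiseless_cherry):
        """Residual pairs (1,-1) at var 1 and (2,0) at var 4 give 2 + 1 = 3.

        The first observation age is left unshifted so the anchored initial
        state (and hence the simulation) is unchanged and contributes zero
        residual; the next two ages carry the hand-chosen residuals.
        """
        study, datasets = noiseless_cherry
        obs, traj = datasets[0]
        ages = np.unique(obs.age_d)[:3]
        idx = [int(np.argmax(obs.age_d == a)) for a in ages]
        shifted = ObservationSet(
            age_d=obs.age_d[idx],
            ss=obs.ss[idx] + np.array([0.0, 1.0, -1.0]),
            st=obs.st[idx] + np.array([0.0, 2.0, 0.0]),
            var_ss=1.0,
            var_st=4.0,
            name="hand",
        )
        truth = study.genotypes["cherry"].template.true_params
        objective = CriterionObjective([(shifted, traj)], Variant.SUGAR)
        assert objective(truth.free_array()) == pytest.approx(3.0, rel=1e-6)

    def test_variance_scaling_identity(self, noiseless_cherry):
        study, datasets = noiseless_cherry
        obs, traj = datasets[0]
        truth = study.genotypes["cherry"].template.true_params
        x = truth.free_array() * 1.1
        f1 = CriterionObjective([(obs, traj)], Variant.SUGAR)(x)
        scaled = dataclasses.replace(obs)
        scaled.var_ss = obs.var_ss * 10
        scaled.var_st = obs.var_st * 10
        f2 = CriterionObjective([(scaled, traj)], Variant.SUGAR)(x)
        assert f2 == pytest.approx(f1 / 10, rel=1e-12)

    def test_dataset_order_invariance(self, noiseless_cherry):
        study, datasets = noiseless_cherry
        truth = study.genotypes["cherry"].template.true_params
        x = truth.free_array() * 1.07
        f1 = CriterionObjective(datasets, Variant.SUGAR)(x)
        f2 = CriterionObjective(datasets[::-1], Variant.SUGAR)(x)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_pooled_variances_match_definition(self, small_study):
        sets = [
            td.observations
            for td in small_study.genotypes["cherry"].treatments.values()
        ]
        var_ss, var_st = pooled_variances(sets)
        all_ss = np.concatenate([s.ss for s in sets])
        assert var_ss == pytest.approx(np.var(all_ss, ddof=1))
        assert sets[0].var_ss == pytest.approx(var_ss)


class TestGA:
    BOUNDS = np.array([[-5.0, 5.0]] * 8)

    @staticmethod
    def sphere(x):
        x = np.atleast_2d(x)
        return (x**2).sum(axis=1)

    def test_sphere_optimum(self):
        cfg = GAConfig(stall_generations=50, max_generations=400)
        res = ga_optimize(self.sphere, self.BOUNDS, cfg, seed=7)
        assert res.criterion < 1e-3

    def test_seed_determinism(self):
        cfg = GAConfig(max_generations=60)
        r1 = ga_optimize(self.sphere, self.BOUNDS, cfg, seed=11)
        r2 = ga_optimize(self.sphere, self.BOUNDS, cfg, seed=11)
        assert np.array_equal(r1.x, r2.x)
        assert r1.criterion == r2.criterion

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ga_optimize(self.sphere, np.array([[1.0, -1.0]]), GAConfig(), seed=0)

    def test_noiseless_recovery_by_construction(self, noiseless_cherry):
        """GA + simplex polish reaches a criterion at least as good as truth's."""
        study, datasets = noiseless_cherry
        objective = CriterionObjective(datasets, Variant.SUGAR)
        truth = study.genotypes["cherry"].template.true_params
        f_truth = objective(truth.free_array())
        bounds = bounds_array(Variant.SUGAR)
        cfg = GAConfig(stall_generations=20, max_generations=60, stall_tol=1e-6)
        best_x, best_f = None, np.inf
        for r in range(3):
            res = ga_optimize(objective, bounds, cfg, seed=np.random.SeedSequence([9, r]))
            if res.criterion < best_f:
                best_f, best_x = res.criterion, res.x
        _, best_f = polish(objective, best_x, bounds, maxfev=6000)
        assert best_f <= f_truth + 1e-6


class TestEnsemble:
    def test_single_repeat_has_no_sd(self, noiseless_cherry):
        _, datasets = noiseless_cherry
        objective = CriterionObjective(datasets, Variant.SUGAR)
        cfg = GAConfig(population_size=20, max_generations=5)
        result = calibrate_ensemble(
            objective, bounds_array(Variant.SUGAR), n_repeats=1, base_seed=0, config=cfg
        )
        assert result.sd is None
        assert result.best_criterion == result.criteria[0]

    def test_best_and_sd_are_order_invariant(self):
        ensemble = np.array([[1.0, 2.0], [3.0, 1.0], [0.5, 5.0]])
        criteria = np.array([3.0, 1.0, 2.0])
        base = CalibrationResult(
            variant=Variant.SUGAR,
            free_names=("a", "b"),
            ensemble=ensemble,
            criteria=criteria,
            seeds=[0, 1, 2],
            feasible=np.ones(3, bool),
        )
        perm = [2, 0, 1]
        permuted = CalibrationResult(
            variant=Variant.SUGAR,
            free_names=("a", "b"),
            ensemble=ensemble[perm],
            criteria=criteria[perm],
            seeds=[perm],
            feasible=np.ones(3, bool),
        )
        assert np.array_equal(base.best_free, permuted.best_free)
        assert np.allclose(base.sd, permuted.sd)


class TestProfileLikelihood:
    def test_quadratic_oracle(self):
        """Exact quadratic criterion gives theta_hat +/- 1.96 s intervals."""
        best = np.array([1.0, -0.5])
        scales = np.array([0.2, 0.05])

        def objective(x):
            return float(np.sum(((np.asarray(x) - best) / scales) ** 2))

        bounds = np.array([[-5.0, 5.0], [-5.0, 5.0]])
        cis = profile_likelihood_ci(objective, best, bounds, n_grid=12)
        for j, ci in enumerate(cis):
            half = 1.959964 * scales[j]
            assert ci["low"] == pytest.approx(best[j] - half, abs=0.02 * scales[j])
            assert ci["high"] == pytest.approx(best[j] + half, abs=0.02 * scales[j])
            assert not ci["open_low"] and not ci["open_high"]
            assert ci["low"] <= best[j] <= ci["high"]

    def test_flat_direction_reported_open(self):
        best = np.array([0.0, 0.0])

        def objective(x):
            return float(x[0] ** 2)  # second coordinate unidentifiable

        bounds = np.array([[-3.0, 3.0], [-3.0, 3.0]])
        cis = profile_likelihood_ci(objective, best, bounds, n_grid=6)
        assert cis[1]["open_low"] and cis[1]["open_high"]
        assert cis[1]["low"] == -3.0 and cis[1]["high"] == 3.0
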