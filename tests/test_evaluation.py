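"""Tests of AIC, RRMSE and the cross-validation machinery."""

import dataclasses
import math

import numpy as np
import pytest

from tomsugar import synth
from tomsugar.calibration import GAConfig
from tomsugar.core import Variant
from tomsugar.evaluation import (
    aic,
    cross_validate,
    evaluate_fit,
    residual_covariance,
    rrmse,
)


class TestResidualCovariance:
    def test_zero_residuals(self):
        y = np.random.default_rng(0).random((2, 6))
        assert np.all(residual_covariance(y, y) == 0.0)

    def test_hand_product(self):
        obs = np.array([[1.0, -1.0], [0.0, 0.0]])
        sim = np.zeros((2, 2))
        with pytest.raises(ValueError):
            residual_covariance(obs, sim)  # n < 3
        obs = np.array([[1.0, -1.0, 0.0], [0.0, 0.0, 0.0]])
        sim = np.zeros((2, 3))
        m = residual_covariance(obs, sim)
        assert np.allclose(m, [[2.0 / 3.0, 0.0], [0.0, 0.0]])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        obs = rng.random((2, 10))
        sim = rng.random((2, 10))
        m = residual_covariance(obs, sim)
        brute = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                for n in range(10):
                    brute[i, j] += (obs[i, n] - sim[i, n]) * (obs[j, n] - sim[j, n])
        assert np.allclose(m, brute / 10)


class TestAic:
    def test_unit_determinant_limit(self):
        m = np.diag([math.e, math.e])
        assert aic(m, k=0, n=10**9) == pytest.approx(2.0, abs=1e-6)

    def test_residual_scaling_shifts_by_logdet(self):
        m = np.array([[2.0, 0.3], [0.3, 1.0]])
        a1 = aic(m, k=5, n=30)
        a2 = aic(m * 100.0, k=5, n=30)  # residuals x10 => covariance x100
        assert a2 - a1 == pytest.approx(math.log(10**4), rel=1e-12)

    def test_parameter_penalty(self):
        m = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert aic(m, k=8, n=30) - aic(m, k=3, n=30) == pytest.approx(
            2 * 5 * 2 / 30, rel=1e-12
        )

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            aic(np.zeros((2, 2)), k=5, n=30)


class TestRrmse:
    def test_perfect_fit(self):
        assert rrmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_case(self):
        assert rrmse([10.0, 10.0], [11.0, 9.0]) == pytest.approx(0.1)

    def test_scale_invariance(self):
        obs = np.array([3.0, 5.0, 9.0])
        sim = np.array([2.5, 5.5, 8.0])
        assert rrmse(obs, sim) == pytest.approx(rrmse(2 * obs, 2 * sim), rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            rrmse([1.0, -1.0], [0.0, 0.0])


@pytest.fixture(scope="module")
def plain_noiseless_datasets():
    """Noiseless plain-variant cherry study for cheap end-to-end evaluation."""
    plain_truth = dataclasses.replace(
        synth.CHERRY_TRUE, alpha=0.0, beta=0.0, gamma=0.0, variant=Variant.SUGAR
    )
    template = dataclasses.replace(synth.cherry_template(), true_params=plain_truth)
    cfg = dataclasses.replace(synth.default_config(), cv=0.0, genotypes=(template,))
    study = synth.generate_study(cfg, seed=8)
    datasets, _ = synth.assemble_datasets(study, "cherry", use_fitted_growth=False)
    return study, datasets


class TestEvaluateFit:
    def test_truth_parameters_fit_noiseless_data(self, plain_noiseless_datasets):
        study, datasets = plain_noiseless_datasets
        truth = study.genotypes["cherry"].template.true_params
        with pytest.raises(ValueError):
            evaluate_fit(datasets, [])
        # zero residuals make the covariance singular: AIC must refuse
        with pytest.raises(ValueError):
            evaluate_fit(datasets, [truth])

    def test_report_shape_with_imperfect_parameters(self, plain_noiseless_datasets):
        study, datasets = plain_noiseless_datasets
        truth = study.genotypes["cherry"].template.true_params
        off = dataclasses.replace(truth, lam=truth.lam * 1.2)
        report = evaluate_fit(datasets, [off])
        assert set(report.index) == {o.name for o, _ in datasets} | {"mean"}
        assert (report["rrmse_ss"] >= 0).all()
        assert report.loc["mean", "rrmse_ss"] == pytest.approx(
            report.drop("mean")["rrmse_ss"].mean()
        )


class TestCrossValidate:
    def test_each_subset_held_out_once(self, plain_noiseless_datasets):
        """Fold bookkeeping: 5 subsets in, 5 folds out, finite RRMSEP.

        With noiseless data from a single global truth no fold should be
        catastrophically worse than the in-sample fit.
        """
        _, datasets = plain_noiseless_datasets
        cfg = GAConfig(population_size=40, stall_generations=10,
                       max_generations=40, stall_tol=1e-6)
        table = cross_validate(
            datasets, Variant.SUGAR, ga_config=cfg, n_repeats=2, base_seed=3,
            polish_best=True,
        )
        held = set(table.index) - {"mean"}
        assert held == {o.name for o, _ in datasets}
        assert np.isfinite(table["rrmsep_ss"]).all()
        assert table.drop("mean")["rrmsep_ss"].max() < 0.1

    def test_misspecified_fold_has_elevated_error(self):
        """A treatment generated by a different truth stands out in RRMSEP."""
        plain_truth = dataclasses.replace(
            synth.CHERRY_TRUE, alpha=0.0, beta=0.0, gamma=0.0, variant=Variant.SUGAR
        )
        template = dataclasses.replace(synth.cherry_template(), true_params=plain_truth)
        cfg = dataclasses.replace(
            synth.default_config(), cv=0.0, genotypes=(template,)
        )
        study = synth.generate_study(cfg, seed=9)
        datasets, _ = synth.assemble_datasets(study, "cherry", use_fitted_growth=False)
        # regenerate one treatment with a deliberately different lambda
        rogue = dataclasses.replace(
            study.genotypes["cherry"].treatments["2007_LL"].template,
            true_params=dataclasses.replace(plain_truth, lam=plain_truth.lam * 1.6),
        )
        rogue_obs = synth.generate_observations(
            rogue,
            study.genotypes["cherry"].treatments["2007_LL"].true_trajectory,
            cv=0.0,
            replicates=4,
            seed=1,
            name="2007_LL",
        )
        rogue_obs.var_ss = datasets[0][0].var_ss
        rogue_obs.var_st = datasets[0][0].var_st
        datasets = [
            (rogue_obs, traj) if obs.name == "2007_LL" else (obs, traj)
            for obs, traj in datasets
        ]
        ga = GAConfig(population_size=40, stall_generations=10,
                      max_generations=40, stall_tol=1e-6)
        table = cross_validate(
            datasets, Variant.SUGAR, ga_config=ga, n_repeats=2, base_seed=4,
            polish_best=True,
        )
        others = table.drop(["mean", "2007_LL"])["rrmsep_ss"]
        assert table.loc["2007_LL", "rrmsep_ss"] > 3 * others.max()

    def test_duplicate_names_rejected(self, plain_noiseless_datasets):
        _, datasets = plain_noiseless_datasets
        bad = [datasets[0], datasets[0]]
        with pytest.raises(ValueError):
            cross_validate(bad, Variant.SUGAR)
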