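"""Likelihood, maximum-likelihood fitting, AIC and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from rrwm import (
    CostSpec,
    FitOptions,
    ModelParams,
    TrialRecord,
    aic_compare,
    crossval_5fold,
    dataset_loglik,
    fit_mle,
    model_spec,
    read_trials,
    trial_loglik,
    write_trials,
)
from rrwm.allocator import AllocationPolicy, optimal_resource_many
from rrwm.synthetic_data import GeneratorSpec, builtin_design, generate, policy_and_params


LIGHT = FitOptions(n_starts=1, maxfev=120)


@pytest.fixture(scope="module")
def rational_data(e6_theta):
    spec = model_spec("rational")
    policy, params = policy_and_params(spec, e6_theta)
    return generate(GeneratorSpec(design=builtin_design("E1", 250), params=params,
                                  policy=policy, seed=11))


class TestLikelihood:
    def test_uniform_branch_is_log_inverse_circumference(self):
        spec = model_spec("nonparametric")
        trial = TrialRecord(subject="s", set_size=4, p_probe=0.25, error=0.0)
        theta = {"J_0": 0.0, "tau": 5.0}
        assert trial_loglik(trial, spec, theta) == pytest.approx(np.log(1 / (2 * np.pi)))

    def test_nonparametric_depends_only_on_condition_entry(self):
        spec = model_spec("nonparametric")
        t = TrialRecord(subject="s", set_size=2, p_probe=0.5, error=0.4)
        a = trial_loglik(t, spec, {"J_0": 3.0, "tau": 2.0})
        b = trial_loglik(t, spec, {"J_0": 3.0, "tau": 2.0})
        assert a == b

    def test_quadrature_oracle_total_loglik(self, e6_theta, rational_data):
        """The 50-bin likelihood should track an independent continuous-
        mixture quadrature of the same model to high accuracy."""
        spec = model_spec("rational")
        params = ModelParams(lambda_=e6_theta["lambda"], tau=e6_theta["tau"],
                             cost=CostSpec("power", e6_theta["beta"]))
        data = rational_data.iloc[:1000]
        ll_pkg = dataset_loglik(data, spec, e6_theta)
        # oracle: p(eps | p_probe) = int VM(eps; J) Gamma(J; J_opt, tau) dJ
        # by 10^4-point quadrature in J, using scipy distributions
        ps = np.sort(data["p_probe"].unique())
        jopts = optimal_resource_many(ps, params, refine="exact")
        tau = e6_theta["tau"]
        ll_ref = 0.0
        from scipy.stats import gamma as gamma_dist
        for p, jopt in zip(ps, jopts):
            errs = data.loc[data["p_probe"] == p, "error_rad"].to_numpy()
            if jopt == 0:
                ll_ref += len(errs) * np.log(1 / (2 * np.pi))
                continue
            shape = jopt / tau
            qs = gamma_dist.ppf(np.linspace(5e-9, 1 - 5e-9, 10_000), shape, scale=tau)
            from rrwm.circdist import j_to_kappa
            kap = j_to_kappa(qs)
            dens = (np.exp(kap[None, :] * (np.cos(errs)[:, None] - 1.0))
                    / (2 * np.pi * special.i0e(kap)[None, :])).mean(axis=1)
            ll_ref += np.log(dens).sum()
        assert ll_pkg == pytest.approx(ll_ref, abs=0.1)

    def test_likelihood_is_proper_density(self, e6_theta, e6_params):
        # the per-trial density integrates to 1 for every condition
        from rrwm import predicted_error_pdf
        eps = np.linspace(-np.pi, np.pi, 20001)
        ps = np.array([0.125, 0.5, 1.0])
        jopts = optimal_resource_many(ps, e6_params, refine="grid")
        for jopt in jopts:
            dens = predicted_error_pdf(eps, jopt, e6_theta["tau"])
            assert np.trapezoid(dens, eps) == pytest.approx(1.0, abs=1e-4)


class TestFitMle:
    def test_deterministic_given_seed(self, rational_data):
        spec = model_spec("fixed_equal")
        a = fit_mle(rational_data, spec, seed=3, options=LIGHT)
        b = fit_mle(rational_data, spec, seed=3, options=LIGHT)
        assert a.theta == b.theta and a.loglik == b.loglik

    def test_fixed_equal_parameter_recovery(self):
        # J_total and tau trade off somewhat at finite n, so the claim is
        # about typical recovery: median error over seeds within 10%
        spec = model_spec("fixed_equal")
        true_theta = {"J_total": 20.0, "tau": 4.0}
        policy, params = policy_and_params(spec, true_theta)
        errs = []
        for seed in range(5):
            data = generate(GeneratorSpec(design=builtin_design("E1", 750),
                                          params=params, policy=policy, seed=seed))
            fit = fit_mle(data, spec, seed=seed, options=LIGHT)
            errs.append(abs(fit.theta["J_total"] - 20.0) / 20.0)
        assert np.median(errs) <= 0.10

    def test_aic_bookkeeping(self, rational_data):
        fit = fit_mle(rational_data, model_spec("emrich_proportional"),
                      seed=0, options=LIGHT)
        assert fit.n_params == 2
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_mle(pd.DataFrame(columns=["subject", "set_size", "p_probe",
                                          "error_rad", "condition_tag"]),
                    model_spec("fixed_equal"))

    def test_nonparametric_recovers_rational_allocation(self, e6_theta, e6_params):
        # free-per-condition resources land on the rational model's optima
        spec = model_spec("rational")
        policy, params = policy_and_params(spec, e6_theta)
        data = generate(GeneratorSpec(design=builtin_design("E1", 2000), params=params,
                                      policy=policy, seed=21))
        np_fit = fit_mle(data, model_spec("nonparametric"), seed=21, options=LIGHT)
        conds = np_fit.theta["conditions"]
        ps = np.array([c[1] for c in conds])
        j_true = optimal_resource_many(ps, e6_params, refine="exact")
        j_hat = np.array([np_fit.theta[f"J_{i}"] for i in range(len(conds))])
        assert j_hat == pytest.approx(j_true, rel=0.15)


class TestCrossValidation:
    def test_fold_partition(self, rational_data):
        n = len(rational_data)
        folds = [np.where(np.arange(n) % 5 == k)[0] for k in range(5)]
        assert sorted(np.concatenate(folds).tolist()) == list(range(n))

    def test_first_fold_holds_out_trials_one_six_eleven(self):
        # 1-based presentation order: fold 1 leaves out trials 1, 6, 11, ...
        n = 10
        held = np.where(np.arange(n) % 5 == 0)[0] + 1
        assert held.tolist() == [1, 6]

    def test_cv_result_structure(self, rational_data):
        spec = model_spec("fixed_equal")
        res = crossval_5fold(rational_data, spec, seed=0, options=LIGHT)
        assert res.cv_loglik == pytest.approx(sum(res.cv_fold_logliks))
        assert len(res.cv_fold_logliks) == 5
        assert res.cv_loglik < res.loglik  # held-out fit is never better

    def test_too_few_trials_rejected(self, rational_data):
        with pytest.raises(ValueError):
            crossval_5fold(rational_data.iloc[:3], model_spec("fixed_equal"))


class TestAicCompare:
    def test_same_model_twice_gives_zero(self, rational_data):
        fit = fit_mle(rational_data, model_spec("fixed_equal"), seed=0, options=LIGHT)
        table = aic_compare({"a": [fit], "b": [fit]}, main="a")
        assert table.loc["b", "delta_aic_mean"] == 0.0

    def test_sign_convention_favors_better_model(self, rational_data):
        # reference model fits better => AIC_main - AIC_alt < 0
        good = fit_mle(rational_data, model_spec("rational"), seed=0, options=LIGHT)
        bad = fit_mle(rational_data, model_spec("fixed_equal"), seed=0, options=LIGHT)
        table = aic_compare({"rational": [good], "fixed_equal": [bad]}, main="rational")
        assert table.loc["fixed_equal", "delta_aic_mean"] < 0

    def test_mismatched_subjects_rejected(self, rational_data):
        fit = fit_mle(rational_data, model_spec("fixed_equal"), seed=0, options=LIGHT)
        with pytest.raises(ValueError):
            aic_compare({"a": [fit], "b": [fit, fit]}, main="a")


class TestTrialTables:
    def test_round_trip(self, tmp_path, rational_data):
        path = tmp_path / "trials.tsv"
        write_trials(rational_data, path)
        back = read_trials(path)
        assert np.allclose(back["error_rad"], rational_data["error_rad"])
        assert back["set_size"].tolist() == rational_data["set_size"].tolist()

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"subject": ["a"], "error_rad": [0.1]}).to_csv(path, sep="\t",
                                                                    index=False)
        with pytest.raises(ValueError):
            read_trials(path)


class TestModelVariants:
    def test_equal_precision_variant_fixes_tau(self, rational_data):
        spec = model_spec("rational", fix_tau=1e-3)
        assert spec.free_params == ("beta", "lambda")
        fit = fit_mle(rational_data, spec, seed=0,
                      options=FitOptions(n_starts=1, maxfev=60))
        assert fit.n_params == 2
        assert "tau" not in fit.theta

    def test_bays_fixed_total_fit_on_cueing_design(self, e6_params):
        # generate from the bays policy on the 3:1 cueing design and refit it
        from rrwm.synthetic_data import builtin_design
        design = builtin_design("E7", 120)
        displays = {c.tag: c.p_vector for c in design.conditions}
        data = generate(GeneratorSpec(design=design, params=e6_params,
                                      policy=AllocationPolicy("bays_fixed_total",
                                                              J_total=12.0), seed=8))
        spec = model_spec("bays_fixed_total", displays=displays)
        opts = FitOptions(n_starts=1, maxfev=60,
                          grid={"beta": [0.5, 2.0], "J_total": [5.0, 15.0, 50.0],
                                "tau": [1.0, 8.0]})
        fit = fit_mle(data, spec, seed=8, options=opts)
        assert fit.n_params == 3  # J_total, tau, plus the cost exponent
        assert np.isfinite(fit.loglik)
        assert 2.0 < fit.theta["J_total"] < 60.0

    def test_unknown_model_name_rejected(self):
        with pytest.raises(ValueError):
            model_spec("slots")
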