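import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from adaptvd.exceptions import (
    PredictionError,
    UndefinedStatisticError,
    ValidationError,
)
from adaptvd.expansion import ExpansionFunction
from adaptvd.fitting import (
    ErrorModel,
    RandomEffects,
    aic,
    bootstrap,
    compare_models,
    count_estimated,
    fit_model,
    neg2loglik,
    predict,
    r_squared,
    weighted_residuals,
)
from adaptvd.model_core import DoseSchedule, PKParameters, StructuralModel
from adaptvd.synthetic_data import StudyDataset, generate_study


def tiny_dataset(obs_rows, schedule=None):
    if schedule is None:
        schedule = DoseSchedule(np.array([1.0]), np.array([25.0]))
    return StudyDataset(
        pd.DataFrame(obs_rows, columns=["animal", "time", "stream", "conc"]),
        schedule,
    )


class TestNeg2LogLik:
    def test_perfect_prediction_contribution(self, ref_model, schedule):
        # one observation with obs == pred and sigma*pred == 1 contributes
        # exactly log(2*pi)
        sim_pred = predict(
            tiny_dataset([("a", 7.0, "serum", 1.0)], schedule), ref_model
        )[0]
        ds = tiny_dataset([("a", 7.0, "serum", sim_pred)], schedule)
        err = ErrorModel(sigma_serum=1.0 / sim_pred, sigma_spleen=1.0)
        assert neg2loglik(ds, ref_model, err) == pytest.approx(
            math.log(2 * math.pi), rel=1e-10
        )

    def test_matches_normal_density_oracle(self, ref_model, schedule, noisy_dataset):
        err = ErrorModel(0.13, 0.21)
        ofv = neg2loglik(noisy_dataset, ref_model, err)
        pred = predict(noisy_dataset, ref_model)
        obs = noisy_dataset.observations
        sig = np.where(obs["stream"] == "serum", err.sigma_serum, err.sigma_spleen)
        oracle = -2.0 * np.sum(
            norm.logpdf(obs["conc"], loc=pred, scale=sig * pred)
        )
        assert ofv == pytest.approx(oracle, rel=1e-10)

    def test_sigma_scaling_identity(self, ref_model, noisy_dataset):
        # scaling both sigmas by c adds 2*N*log(c) and rescales residuals
        err = ErrorModel(0.1, 0.1)
        c = 2.5
        err_c = ErrorModel(0.1 * c, 0.1 * c)
        ofv = neg2loglik(noisy_dataset, ref_model, err)
        ofv_c = neg2loglik(noisy_dataset, ref_model, err_c)
        pred = predict(noisy_dataset, ref_model)
        r2sum = np.sum(
            ((noisy_dataset.observations["conc"] - pred) / (0.1 * pred)) ** 2
        )
        n = noisy_dataset.n_obs
        expected = ofv + 2 * n * math.log(c) + (1 / c**2 - 1) * r2sum
        assert ofv_c == pytest.approx(expected, rel=1e-10)

    def test_observation_before_first_dose_errors(self, ref_model):
        ds = tiny_dataset([("a", 0.5, "serum", 1.0)])
        with pytest.raises(PredictionError, match="animal a"):
            neg2loglik(ds, ref_model, ErrorModel(0.1, 0.1))


class TestAic:
    def test_simple(self):
        assert aic(100.0, 5) == 110.0

    def test_degenerate(self):
        assert aic(0.0, 0) == 0.0

    def test_negative_p_rejected(self):
        with pytest.raises(ValidationError):
            aic(1.0, -1)

    def test_parameter_count_deltas(self, base_model):
        # expansion models add exactly their expansion parameters
        fixed = ("v1", "k12")
        base = StructuralModel(base_model.parameters)
        p_base = count_estimated(base, fixed)
        linear = StructuralModel(
            base_model.parameters, ExpansionFunction.linear(0.2)
        )
        hill = StructuralModel(
            base_model.parameters, ExpansionFunction.hill_exp(2.0, 49.0, 3.7)
        )
        three = StructuralModel(
            PKParameters(v1=2.43, v2=0.005, k=0.1, k12=0.183, k21=1.0,
                         v3=0.5, k13=0.05, k31=0.02)
        )
        assert count_estimated(linear, fixed) - p_base == 1
        assert count_estimated(hill, fixed) - p_base == 3
        assert count_estimated(three, fixed) - p_base == 3


class TestRSquared:
    def test_perfect(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_prediction_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([1, 2, 3], [2, 2, 2])

    def test_hand_computed_toy(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9643, abs=1e-4)

    def test_too_few(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([1.0], [1.0])


class TestWeightedResiduals:
    def test_zero_and_unit_residuals(self, ref_model, schedule):
        pred = predict(
            tiny_dataset([("a", 7.0, "spleen", 1.0)], schedule), ref_model
        )[0]
        sigma = 0.2
        ds = tiny_dataset(
            [("a", 7.0, "spleen", pred), ("b", 7.0, "spleen", pred * (1 + sigma))],
            schedule,
        )
        res = weighted_residuals(ds, ref_model, ErrorModel(0.1, sigma))
        assert res["wres"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["wres"].iloc[1] == pytest.approx(1.0, rel=1e-9)


class TestFit:
    def test_noise_free_recovery(self, clean_dataset, ref_model):
        fit = fit_model(
            clean_dataset, ref_model, fixed=("hill",),
            n_multistart=2, seed=1, dt_max=0.25, compute_cv=False,
        )
        truth = {**ref_model.parameters.to_dict(), **ref_model.expansion.params}
        for name, est in fit.estimates.items():
            assert est == pytest.approx(truth[name], rel=0.01), name

    def test_all_fixed_returns_inits(self, clean_dataset, ref_model):
        err = ErrorModel(0.1, 0.1)
        all_names = tuple(ref_model.parameters.names) + tuple(
            ref_model.expansion.params
        )
        fit = fit_model(clean_dataset, ref_model, fixed=all_names, error=err)
        assert fit.estimates == {}
        assert fit.p == 0
        assert fit.ofv == pytest.approx(
            neg2loglik(clean_dataset, ref_model, err), rel=1e-12
        )

    def test_all_fixed_needs_error_model(self, clean_dataset, ref_model):
        all_names = tuple(ref_model.parameters.names) + tuple(
            ref_model.expansion.params
        )
        with pytest.raises(ValidationError):
            fit_model(clean_dataset, ref_model, fixed=all_names)

    def test_ofv_never_increases_on_release(self, noisy_dataset, ref_model):
        constrained = fit_model(
            noisy_dataset, ref_model, fixed=("hill", "k21"),
            n_multistart=2, seed=3, dt_max=0.25, compute_cv=False,
        )
        released = fit_model(
            noisy_dataset, ref_model, fixed=("hill",),
            init=constrained.estimates,
            n_multistart=2, seed=3, dt_max=0.25, compute_cv=False,
        )
        assert released.ofv <= constrained.ofv + 1e-6

    def test_aic_identity(self, noisy_dataset, ref_model):
        fit = fit_model(
            noisy_dataset, ref_model, fixed=("hill",),
            n_multistart=1, seed=0, dt_max=0.25, compute_cv=False,
        )
        assert fit.aic == pytest.approx(fit.ofv + 2 * fit.p)
        # 5 structural/expansion estimates + 2 profiled sigmas
        assert fit.p == 7

    def test_soluble_phase_workflow(self, ref_model):
        # truncated 4-week fit of the constant-Vd model, then V1/K12 frozen
        from adaptvd.synthetic_data import truncate_study

        ds = generate_study(ref_model, sigma_serum=0.05, sigma_spleen=0.05,
                            seed=11, dt_max=0.25)
        soluble = truncate_study(ds, 28.0)
        assert set(soluble.observations["time"]) == {7.0, 14.0, 28.0}
        free = StructuralModel(PKParameters(**{
            n: getattr(ref_model.parameters, n)
            for n in ("v1", "v2", "k", "k12", "k21")
        }))
        sol_fit = fit_model(soluble, free, n_multistart=2, seed=2,
                            dt_max=0.25, compute_cv=False)
        assert {"v1", "k12"} <= set(sol_fit.estimates)
        full = fit_model(
            ds,
            ref_model.with_parameters(
                v1=sol_fit.estimates["v1"], k12=sol_fit.estimates["k12"]
            ),
            fixed=("hill",), n_multistart=2, seed=2, dt_max=0.25,
            compute_cv=False,
        )
        assert full.fixed["v1"] == pytest.approx(sol_fit.estimates["v1"])
        assert "v1" not in full.estimates

    def test_cv_reported(self, noisy_dataset, ref_model):
        fit = fit_model(
            noisy_dataset, ref_model, fixed=("hill",),
            n_multistart=1, seed=0, dt_max=0.25,
        )
        assert set(fit.cv_percent) == set(fit.estimates)
        assert fit.cv_source in ("hessian", "unavailable")


class TestBootstrap:
    def test_determinism(self, noisy_dataset, ref_model):
        kw = dict(seed=5, fixed=("hill",), n_multistart=1, dt_max=0.25,
                  maxfev=400)
        b1 = bootstrap(noisy_dataset, ref_model, 10, **kw)
        b2 = bootstrap(noisy_dataset, ref_model, 10, **kw)
        assert b1.table.equals(b2.table)
        assert b1.n_failed == b2.n_failed

    def test_min_reps_enforced(self, noisy_dataset, ref_model):
        with pytest.raises(ValidationError):
            bootstrap(noisy_dataset, ref_model, 0)

    def test_preserves_design(self, noisy_dataset, ref_model, monkeypatch):
        # every resample keeps the per-day cohort sizes
        seen = []
        import adaptvd.fitting as F

        orig = F.fit_model

        def spy(ds, *a, **kw):
            seen.append(ds.observations.groupby("time")["animal"].nunique())
            return orig(ds, *a, **kw)

        monkeypatch.setattr(F, "fit_model", spy)
        bootstrap(noisy_dataset, ref_model, 10, seed=2, fixed=("hill",),
                  n_multistart=1, dt_max=0.25, maxfev=200)
        target = noisy_dataset.observations.groupby("time")["animal"].nunique()
        for counts in seen:
            assert counts.equals(target)


class TestCompare:
    def test_identical_models_tie_stable(self, noisy_dataset, ref_model):
        table = compare_models(
            noisy_dataset,
            {"first": ref_model, "second": ref_model},
            fixed=("hill",), n_multistart=1, seed=0, dt_max=0.25,
            compute_cv=False,
        )
        assert list(table["name"]) == ["first", "second"]
        assert table["aic"].iloc[0] == pytest.approx(table["aic"].iloc[1])

    def test_failure_recorded_not_fatal(self, noisy_dataset, ref_model):
        broken = StructuralModel(
            PKParameters(v1=2.43, v2=0.005, k=0.1, k12=0.183, k21=1.0)
        )
        table = compare_models(
            noisy_dataset,
            {"ok": ref_model, "broken": broken},
            inits={"broken": {"k": 1e9}},  # beyond the step budget
            fixed=("hill", "v1", "v2", "k12", "k21"),
            n_multistart=1, seed=0, dt_max=0.25, compute_cv=False,
        )
        row = table[table["name"] == "broken"].iloc[0]
        assert row["error"] != ""
        assert np.isnan(row["aic"])

    def test_needs_two_models(self, noisy_dataset, ref_model):
        with pytest.raises(ValidationError):
            compare_models(noisy_dataset, {"only": ref_model})

    def test_full_family_table(self, noisy_dataset, ref_model):
        params = ref_model.parameters
        members = {
            "base": StructuralModel(params),
            "linear": StructuralModel(params, ExpansionFunction.linear(0.05)),
            "hill_exp": StructuralModel(
                params, ExpansionFunction.hill_exp(2.0, 60.0, 3.71)),
            "logistic": StructuralModel(
                params, ExpansionFunction.logistic(12.0, 0.07, 60.0)),
            "sqrt_sigmoid": StructuralModel(
                params, ExpansionFunction.sqrt_sigmoid(12.0, 60.0, 9.0)),
            "three_cmt": StructuralModel(PKParameters(
                v1=2.43, v2=0.00708, k=0.229, k12=0.183, k21=3.36,
                v3=0.5, k13=0.05, k31=0.02, fixed=frozenset({"v1", "k12"}))),
        }
        table = compare_models(
            noisy_dataset, members,
            fixed=("hill", "m2", "m3", "b2", "b3"),
            n_multistart=1, seed=0, dt_max=0.25, compute_cv=False,
            maxfev=300,
        )
        assert len(table) == 6
        assert table["aic"].is_monotonic_increasing


class TestRandomEffects:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValidationError):
            RandomEffects({"emax": -0.1})
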