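"""Standardisation, logistic fitting, screening, published equations."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from neohrv.exceptions import (
    DegenerateOutcomeError,
    MissingTermError,
    SeparationWarning,
    TransformError,
)
from neohrv.models import (
    LogisticModel,
    StandardizationRecipe,
    StudyConfig,
    fit_logistic,
    predict_prob,
    published_model,
    run_study,
    standardize,
    univariable_screen,
)


class TestStandardize:
    def test_identity_closed_form(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, recipe = standardize(df, ["x"], log10_features=())
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert recipe.transforms["x"] == "identity"

    def test_log10_closed_form(self):
        df = pd.DataFrame({"x": [10.0, 100.0, 1000.0]})
        out, recipe = standardize(df, ["x"], log10_features=("x",))
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert recipe.transforms["x"] == "log10"

    def test_reapplying_recipe_is_idempotent(self, rng):
        df = pd.DataFrame({"x": rng.lognormal(0, 1, 50), "y": rng.normal(0, 2, 50)})
        out1, recipe = standardize(df, ["x", "y"], log10_features=("x",))
        out2 = recipe.apply(df)
        pd.testing.assert_frame_equal(out1, out2)

    def test_nonpositive_log_feature_names_offender(self):
        df = pd.DataFrame({"hf": [1.0, -2.0, 3.0]})
        with pytest.raises(TransformError, match="hf"):
            standardize(df, ["hf"], log10_features=("hf",))

    def test_recipe_roundtrips_through_dict(self, rng):
        df = pd.DataFrame({"x": rng.lognormal(0, 1, 30)})
        _, recipe = standardize(df, ["x"], log10_features=("x",))
        again = StandardizationRecipe.from_dict(recipe.to_dict())
        pd.testing.assert_frame_equal(recipe.apply(df), again.apply(df))


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # cells: exposed/cases a=20, exposed/controls b=10, c=5, d=15
        x = np.array([1] * 30 + [0] * 20)
        y = np.array([1] * 20 + [0] * 10 + [1] * 5 + [0] * 15)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.coefficients["x"] == pytest.approx(math.log(20 * 15 / (10 * 5)), abs=1e-6)
        # intercept is the log-odds among unexposed
        assert m.intercept == pytest.approx(math.log(5 / 15), abs=1e-6)

    def test_parameter_recovery_simulation(self, rng):
        beta0, beta1, beta2 = -0.5, 0.8, -0.6
        x1 = rng.normal(0, 1, 5000)
        x2 = rng.normal(0, 1, 5000)
        eta = beta0 + beta1 * x1 + beta2 * x2
        y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(int)
        m = fit_logistic(pd.DataFrame({"x1": x1, "x2": x2}), y)
        for name, truth in [("x1", beta1), ("x2", beta2)]:
            assert abs(m.coefficients[name] - truth) < 3 * m.se[name]

    def test_mean_estimate_bias_small_over_cohorts(self):
        """ML logistic coefficients are nearly unbiased at n = 1000."""
        truth = {"x1": 0.7, "x2": -0.5}
        est = {k: [] for k in truth}
        gen = np.random.default_rng(5150)
        for _ in range(100):
            x1, x2 = gen.normal(0, 1, (2, 1000))
            eta = -0.3 + truth["x1"] * x1 + truth["x2"] * x2
            y = (gen.random(1000) < 1 / (1 + np.exp(-eta))).astype(int)
            m = fit_logistic(pd.DataFrame({"x1": x1, "x2": x2}), y)
            for k in truth:
                est[k].append(m.coefficients[k])
        for k, t in truth.items():
            assert abs(np.mean(est[k]) - t) < 0.05 * abs(t)

    def test_perfect_separation_warns(self):
        x = np.array([0.0, 0.1, 0.2, 0.8, 0.9, 1.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(SeparationWarning):
            fit_logistic(pd.DataFrame({"x": x}), y)

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), np.ones(3))

    def test_complete_case_restriction_is_stable(self, rng):
        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(int)
        df = pd.DataFrame({"x": x})
        m1 = fit_logistic(df, y)
        df2 = pd.concat([df, pd.DataFrame({"x": [np.nan]}, index=[999])])
        y2 = np.append(y, 1)
        m2 = fit_logistic(df2, pd.Series(y2, index=df2.index))
        assert m2.coefficients["x"] == pytest.approx(m1.coefficients["x"], abs=1e-12)
        assert m2.n_dropped == 1
        assert m2.n_used == 200


class TestScreen:
    def test_or_equals_exp_coefficient(self, rng):
        x = rng.normal(0, 1, 150)
        y = (rng.random(150) < 1 / (1 + np.exp(-x))).astype(int)
        data = pd.DataFrame({"x": x, "y": y})
        res = univariable_screen(data, "y", ["x"])
        row = res.table.loc["x"]
        assert row["or"] == pytest.approx(math.exp(row["coef"]), rel=1e-12)
        assert row["or_ci_low"] < row["or"] < row["or_ci_high"]

    def test_duplicated_predictor_pruned(self, rng):
        x = rng.normal(0, 1, 120)
        y = (rng.random(120) < 1 / (1 + np.exp(-1.5 * x))).astype(int)
        data = pd.DataFrame({"a": x, "b": x.copy(), "y": y})
        res = univariable_screen(data, "y", ["a", "b"])
        assert res.table["kept"].sum() == 1
        pruned = res.table[~res.table["kept"]]
        assert (pruned["pruned_by"] != "").all()

    def test_null_predictor_eligibility_rate(self):
        """An unrelated predictor passes the p < 0.25 gate about 25% of
        the time."""
        gen = np.random.default_rng(99)
        eligible = 0
        reps = 200
        for _ in range(reps):
            x = gen.normal(0, 1, 400)
            y = gen.integers(0, 2, 400)
            if y.min() == y.max():
                continue
            res = univariable_screen(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
            eligible += int(res.table.loc["x", "eligible"])
        assert 0.25 * reps - 2.5 * math.sqrt(reps * 0.25 * 0.75) <= eligible
        assert eligible <= 0.25 * reps + 2.5 * math.sqrt(reps * 0.25 * 0.75)


class TestPublishedModels:
    def test_hrv_model_intercept_only_log_odds(self):
        m = published_model("hrv")
        row = dict.fromkeys(m.terms, 0.0)
        assert m.linear_predictor(row) == pytest.approx(0.49)

    def test_combined_model_worked_example(self):
        """Zero standardized HRV features, no foetal distress, GA 40 weeks,
        non-emergency delivery, Apgar-5 of 5, ventilated at 10 min."""
        m = published_model("combined")
        row = dict.fromkeys(m.terms, 0.0)
        row.update({"ga_weeks": 40.0, "apgar5": 5.0, "ventilation_10min": 1.0})
        expected = 11.49 - 0.28 * 40 - 0.06 * 5 + 2.19
        assert m.linear_predictor(row) == pytest.approx(expected, abs=1e-12)
        assert predict_prob(m, row) == pytest.approx(1 / (1 + math.exp(-expected)))

    def test_printed_odds_ratios_consistent_with_coefficients(self):
        """exp(printed coefficient) agrees with the printed OR column to
        within the propagation of two-decimal rounding."""
        for name in ("hrv", "clinical", "combined"):
            m = published_model(name)
            for term, printed in m.printed_or.items():
                tol = 0.0051 * printed + 0.00501
                assert abs(math.exp(m.coefficients[term]) - printed) <= tol, (
                    name,
                    term,
                )

    def test_unknown_model_name(self):
        with pytest.raises(KeyError):
            published_model("bogus")


class TestPredict:
    def test_zero_linear_predictor_gives_half(self):
        m = LogisticModel(terms=["x"], intercept=0.0, coefficients={"x": 1.0})
        assert predict_prob(m, {"x": 0.0}) == 0.5

    def test_probability_monotone_in_eta(self):
        m = LogisticModel(terms=["x"], intercept=0.0, coefficients={"x": 1.0})
        probs = [predict_prob(m, {"x": v}) for v in np.linspace(-30, 30, 13)]
        assert all(b > a for a, b in zip(probs, probs[1:]))
        assert probs[-1] < 1.0 + 1e-12

    def test_missing_term_is_named(self):
        m = published_model("clinical")
        with pytest.raises(MissingTermError, match="ga_weeks"):
            predict_prob(m, {"foetal_distress": 0.0})

    def test_fitted_probabilities_average_to_prevalence(self, rng):
        x = rng.normal(0, 1, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-0.8 * x - 0.3))).astype(int)
        df = pd.DataFrame({"x": x})
        m = fit_logistic(df, y)
        probs = predict_prob(m, df)
        assert np.mean(probs) == pytest.approx(y.mean(), abs=1e-6)

    def test_model_json_roundtrip(self, tmp_path, rng):
        x = rng.normal(0, 1, 100)
        y = (rng.random(100) < 0.5).astype(int)
        y[:2] = [0, 1]
        df = pd.DataFrame({"x": x})
        m = fit_logistic(df, y)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = LogisticModel.from_json(path)
        assert m2.coefficients == m.coefficients
        assert np.allclose(predict_prob(m2, df), predict_prob(m, df))
        assert json.loads(path.read_text())["provenance"] == "fitted"


class TestRunStudy:
    def test_contrasted_cohort_smoke(self, small_cohort):
        from neohrv.features import extract_cohort

        feats = extract_cohort(small_cohort.rr)
        res = run_study(feats, small_cohort.clinical)
        assert set(res.models) == {"hrv", "clinical", "combined"}
        assert res.n_complete <= res.n_total
        assert all(0.0 <= ev.auroc <= 1.0 for ev in res.evaluations.values())
        # determinism: same inputs, same report
        res2 = run_study(feats, small_cohort.clinical)
        assert res.report() == res2.report()

    def test_null_cohort_aurocs_near_chance(self):
        """With no group contrast anywhere, apparent AUROCs of all three
        models stay near 0.5 (allowing small-sample optimism)."""
        gen = np.random.default_rng(31)
        n = 160
        feats = pd.DataFrame(
            {
                "mean_nn_ms": gen.normal(550, 40, n),
                "hf_power_ms2": gen.lognormal(2, 0.8, n),
                "lf_hf_ratio": gen.lognormal(1.5, 0.7, n),
                "tinn_ms": gen.lognormal(4.3, 0.4, n),
                "mse_complexity_index": gen.normal(10, 2, n),
                "mse_short_slope": gen.normal(-0.2, 0.05, n),
            },
            index=[f"s{i:04d}" for i in range(n)],
        )
        clinical = pd.DataFrame(
            {
                "moderate_severe": gen.integers(0, 2, n),
                "ga_weeks": gen.normal(40, 1.2, n),
                "apgar5": np.clip(np.round(gen.normal(4, 2, n)), 0, 10),
                "ventilation_10min": (gen.random(n) < 0.6).astype(float),
                "emergency_delivery": (gen.random(n) < 0.6).astype(float),
                "male": (gen.random(n) < 0.5).astype(float),
            },
            index=feats.index,
        )
        res = run_study(feats, clinical)
        for ev in res.evaluations.values():
            assert abs(ev.auroc - 0.5) < 0.17

    def test_subgroup_filter_reduces_n(self, small_cohort):
        from neohrv.features import extract_cohort

        feats = extract_cohort(small_cohort.rr)
        full = run_study(feats, small_cohort.clinical)
        cooled = run_study(feats, small_cohort.clinical, StudyConfig(subgroup="cooled"))
        assert cooled.n_total <= full.n_total
        with pytest.raises(ValueError):
            run_study(feats, small_cohort.clinical, StudyConfig(subgroup="nope"))
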