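import numpy as np
import pandas as pd
import pytest

from deltami import (
    Column,
    ImputationConfig,
    Schema,
    StudyTable,
    build_design,
    draw_parameters,
    fit_imputation_model,
)


def table_from(df, schema):
    return StudyTable(df.reset_index(drop=True), schema)


@pytest.fixture
def wide_schema():
    return Schema(
        [
            Column("y", "binary"),
            Column("edu", "categorical", ("primary", "none", "lower", "upper", "college")),
            Column("age", "categorical", tuple("abcdef")),
            Column("region", "categorical", tuple("wxyz")),
            Column("z", "binary"),
        ]
    )


class TestBuildDesign:
    def test_five_level_categorical_gives_four_dummies(self, wide_schema):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, 100).astype(float),
                "edu": rng.choice(["primary", "none", "lower", "upper", "college"], 100),
                "age": rng.choice(list("abcdef"), 100),
                "region": rng.choice(list("wxyz"), 100),
                "z": rng.integers(0, 2, 100).astype(float),
            }
        )
        t = table_from(df, wide_schema)
        X, labels, dropped = build_design(t, ["edu"])
        assert labels[0] == "Intercept"
        assert len(labels) == 1 + 4
        assert not dropped

    def test_age_region_width_is_nine_columns(self, wide_schema):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, 200).astype(float),
                "edu": "primary",
                "age": rng.choice(list("abcdef"), 200),
                "region": rng.choice(list("wxyz"), 200),
                "z": 0.0,
            }
        )
        t = table_from(df, wide_schema)
        X, labels, _ = build_design(t, ["age", "region"])
        assert X.shape[1] == 1 + 5 + 3  # intercept + 6 age bands + 4 regions

    def test_constant_predictor_dropped_with_width_reduced(self, wide_schema):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, 50).astype(float),
                "edu": "primary",  # constant -> all its dummies dropped
                "age": rng.choice(list("abcdef"), 50),
                "region": "w",
                "z": rng.integers(0, 2, 50).astype(float),
            }
        )
        t = table_from(df, wide_schema)
        X, labels, dropped = build_design(t, ["edu", "age", "z"])
        assert "edu" in dropped
        assert all(not l.startswith("edu") for l in labels)

    def test_reference_override_changes_absorbed_level(self, wide_schema):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, 100).astype(float),
                "edu": rng.choice(["primary", "none"], 100),
                "age": "a",
                "region": "w",
                "z": 0.0,
            }
        )
        t = table_from(df, wide_schema)
        _, labels, _ = build_design(t, ["edu"], reference_overrides={"edu": "none"})
        assert "edu[primary]" in labels
        assert "edu[none]" not in labels


class TestFitImputationModel:
    def test_intercept_only_mle_is_log_odds_of_observed(self):
        t = StudyTable(
            pd.DataFrame({"y": [1.0] * 3 + [0.0] * 7 + [np.nan] * 4, "z": 0.5}),
            Schema([Column("y", "binary"), Column("z", "binary")]),
        )
        # constant predictor is dropped -> intercept-only fit
        t.data["z"] = 0.0
        cfg = ImputationConfig(predictors=("z",), M=1, seed=0)
        fitted = fit_imputation_model(t, "y", cfg)
        fit = fitted.strata[None]
        assert fit.coef[0] == pytest.approx(np.log(3 / 7), abs=1e-6)

    def test_saturated_binary_covariate_slope_is_log_odds_ratio(self):
        a, b, c, d = 5, 15, 3, 27  # exposed 1s/0s, unexposed 1s/0s
        y = [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d
        x = [1.0] * (a + b) + [0.0] * (c + d)
        t = StudyTable(
            pd.DataFrame({"y": y, "x": x}),
            Schema([Column("y", "binary"), Column("x", "binary")]),
        )
        cfg = ImputationConfig(predictors=("x",), M=1, seed=0)
        fit = fit_imputation_model(t, "y", cfg).strata[None]
        slope = fit.coef[fit.labels.index("x")]
        assert slope == pytest.approx(np.log(a * d / (b * c)), abs=1e-5)

    def test_saturated_fit_reproduces_cell_frequencies(self):
        """On a saturated design the fitted probabilities equal observed
        cell frequencies (independent oracle: direct frequency counts)."""
        rng = np.random.default_rng(5)
        g = rng.choice(["p", "q", "r"], 500)
        probs = {"p": 0.2, "q": 0.5, "r": 0.8}
        y = (rng.random(500) < np.vectorize(probs.get)(g)).astype(float)
        schema = Schema([Column("y", "binary"), Column("g", "categorical", ("p", "q", "r"))])
        t = StudyTable(pd.DataFrame({"y": y, "g": g}), schema)
        cfg = ImputationConfig(predictors=("g",), M=1, seed=0)
        fit = fit_imputation_model(t, "y", cfg).strata[None]
        from scipy.special import expit

        for lev in ("p", "q", "r"):
            lp = fit.coef[0]
            if f"g[{lev}]" in fit.labels:
                lp = lp + fit.coef[fit.labels.index(f"g[{lev}]")]
            observed_freq = y[g == lev].mean()
            assert expit(lp) == pytest.approx(observed_freq, abs=1e-6)

    def test_fit_ignores_unobserved_rows_covariates(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.3 + 0.3 * x).astype(float)
        y[:80] = np.nan
        schema = Schema([Column("y", "binary"), Column("x", "binary")])
        t1 = StudyTable(pd.DataFrame({"y": y, "x": x}), schema)
        x2 = x.copy()
        x2[:80] = rng.permutation(x2[:80])  # permute covariates of missing rows
        t2 = StudyTable(pd.DataFrame({"y": y, "x": x2}), schema)
        cfg = ImputationConfig(predictors=("x",), M=1, seed=0)
        f1 = fit_imputation_model(t1, "y", cfg).strata[None]
        f2 = fit_imputation_model(t2, "y", cfg).strata[None]
        np.testing.assert_array_equal(f1.coef, f2.coef)

    def test_degenerate_target_raises(self):
        t = StudyTable(
            pd.DataFrame({"y": [1.0] * 5 + [np.nan] * 2, "x": [0.0, 1.0] * 3 + [1.0]}),
            Schema([Column("y", "binary"), Column("x", "binary")]),
        )
        cfg = ImputationConfig(predictors=("x",), M=1, seed=0)
        with pytest.raises(ValueError, match="degenerate target"):
            fit_imputation_model(t, "y", cfg)

    def test_near_separation_triggers_penalized_engine(self):
        # an auxiliary level almost determines the target: 59/60 positives
        rng = np.random.default_rng(7)
        y = np.concatenate([np.ones(59), [0.0], np.zeros(60), np.ones(0)])
        x = np.concatenate([np.ones(60), np.zeros(60)])
        # make it fully separated within one cell by flipping the one 0
        y[59] = 1.0
        schema = Schema([Column("y", "binary"), Column("x", "binary")])
        t = StudyTable(pd.DataFrame({"y": y, "x": x}), schema)
        cfg = ImputationConfig(predictors=("x",), M=1, seed=0)
        fit = fit_imputation_model(t, "y", cfg).strata[None]
        assert fit.engine == "penalized"
        assert np.all(np.isfinite(fit.coef))
        assert np.all(np.isfinite(np.diag(fit.vcov)))

    def test_stratified_fit_produces_one_model_per_level(self):
        rng = np.random.default_rng(8)
        n = 400
        s = rng.choice(["m", "f"], n)
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.4).astype(float)
        y[:50] = np.nan
        schema = Schema(
            [Column("y", "binary"), Column("x", "binary"),
             Column("s", "categorical", ("m", "f"))]
        )
        t = StudyTable(pd.DataFrame({"y": y, "x": x, "s": s}), schema)
        cfg = ImputationConfig(predictors=("x",), M=1, seed=0, strata="s")
        fitted = fit_imputation_model(t, "y", cfg)
        assert set(fitted.strata) == {"m", "f"}


class TestDrawParameters:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.3 + 0.2 * x).astype(float)
        y[:100] = np.nan
        schema = Schema([Column("y", "binary"), Column("x", "binary")])
        t = StudyTable(pd.DataFrame({"y": y, "x": x}), schema)
        cfg = ImputationConfig(predictors=("x",), M=5, seed=123)
        return fit_imputation_model(t, "y", cfg)

    def test_same_seed_and_index_reproduce_exactly(self, fitted):
        d1 = draw_parameters(fitted, None, m=3)
        d2 = draw_parameters(fitted, None, m=3)
        np.testing.assert_array_equal(d1.coef, d2.coef)

    def test_different_m_gives_different_draws(self, fitted):
        d1 = draw_parameters(fitted, None, m=0)
        d2 = draw_parameters(fitted, None, m=1)
        assert not np.array_equal(d1.coef, d2.coef)

    def test_zero_vcov_returns_mle_exactly(self, fitted):
        fit = fitted.strata[None]
        fit.vcov = np.zeros_like(fit.vcov)
        d = draw_parameters(fitted, None, m=0)
        np.testing.assert_array_equal(d.coef, fit.coef)

    def test_draw_mean_converges_to_mle(self, fitted):
        fit = fitted.strata[None]
        draws = np.stack([draw_parameters(fitted, None, m=m).coef for m in range(2000)])
        se = np.sqrt(np.diag(fit.vcov) / 2000)
        assert np.all(np.abs(draws.mean(axis=0) - fit.coef) < 4 * se)
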