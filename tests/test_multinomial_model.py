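"""Multinomial logistic fitting, Wald inference, prediction, and diagnostics."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import swaywave as sw
from swaywave.errors import ParameterError, RankDeficientError, ValidationError
from swaywave.multinomial_model import INTERCEPT


def simulate_multinomial(n, beta, seed, class_names=("group1", "group2", "group3")):
    """Draw labels from the softmax model with known coefficients.

    ``beta`` has shape (K-1, p+1); the last class is the reference.
    """
    rng = np.random.default_rng(seed)
    p = beta.shape[1] - 1
    X = rng.standard_normal((n, p))
    Xd = np.column_stack([np.ones(n), X])
    eta = np.column_stack([Xd @ b for b in beta] + [np.zeros(n)])
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
    u = rng.random(n)
    y = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
    df = pd.DataFrame(X, columns=[f"x{j+1}" for j in range(p)])
    df["group"] = np.asarray(class_names)[y]
    return df


BETA_3CLASS = np.array(
    [[0.4, 1.0, -1.0, 0.3, 0.0], [-0.3, 0.5, 0.8, -0.6, 0.4]]
)


class TestFit:
    def test_intercept_only_recovers_class_frequencies(self):
        labels = ["group1"] * 18 + ["group2"] * 20 + ["group3"] * 7
        fit = sw.fit_multinomial(pd.DataFrame({"group": labels}),
                                 reference="group3", predictors=[])
        probs, _ = sw.predict_group(fit, {})
        assert probs["group1"] == pytest.approx(18 / 45, abs=1e-9)
        assert probs["group2"] == pytest.approx(20 / 45, abs=1e-9)
        assert probs["group3"] == pytest.approx(7 / 45, abs=1e-9)

    def test_binary_case_matches_direct_likelihood_oracle(self):
        df = simulate_multinomial(
            400, np.array([[0.5, 1.2, -0.7]]), seed=4,
            class_names=("case", "control"),
        )
        fit = sw.fit_multinomial(df, reference="control")
        X = np.column_stack([np.ones(len(df)), df[["x1", "x2"]].to_numpy()])
        y = (df["group"] == "case").to_numpy(float)

        def nll(b):  # independent binary logit, plain likelihood maximization
            eta = X @ b
            return np.sum(np.log1p(np.exp(-np.abs(eta)))
                          + np.where(eta > 0, 0, -eta) + (1 - y) * eta)

        oracle = optimize.minimize(nll, np.zeros(3), method="BFGS",
                                   options={"gtol": 1e-10}).x
        assert np.max(np.abs(fit.beta[0] - oracle)) < 1e-6

    def test_matches_statsmodels_coefficients_and_se(self):
        import statsmodels.api as sm

        df = simulate_multinomial(300, BETA_3CLASS, seed=1)
        fit = sw.fit_multinomial(df, reference="group3")
        cat = pd.Categorical(df["group"],
                             categories=["group3", "group1", "group2"])
        Xd = np.column_stack([np.ones(len(df)),
                              df[[f"x{j}" for j in range(1, 5)]].to_numpy()])
        ref = sm.MNLogit(cat.codes, Xd).fit(disp=0, method="newton")
        assert np.max(np.abs(fit.beta - np.asarray(ref.params).T)) < 1e-6
        assert np.max(np.abs(fit.se - np.asarray(ref.bse).T)) < 1e-6

    def test_loglik_trace_is_monotone(self):
        df = simulate_multinomial(200, BETA_3CLASS, seed=2)
        fit = sw.fit_multinomial(df, reference="group3")
        assert fit.converged
        assert np.all(np.diff(fit.loglik_trace) >= -1e-12)

    def test_ci_brackets_estimate(self):
        df = simulate_multinomial(200, BETA_3CLASS, seed=3)
        fit = sw.fit_multinomial(df, reference="group3")
        assert np.all(fit.ci_low <= fit.beta)
        assert np.all(fit.beta <= fit.ci_high)

    def test_ridge_shrinks_coefficients(self):
        df = simulate_multinomial(150, BETA_3CLASS, seed=5)
        mle = sw.fit_multinomial(df, reference="group3")
        ridge = sw.fit_multinomial(df, reference="group3", penalty=5.0)
        assert (ridge.beta[:, 1:] ** 2).sum() < (mle.beta[:, 1:] ** 2).sum()
        assert ridge.converged

    def test_separation_reported_and_fixed_by_penalty(self):
        x = np.r_[np.linspace(-2, -0.5, 15), np.linspace(0.5, 2, 15)]
        df = pd.DataFrame({"x1": x, "group": ["a"] * 15 + ["b"] * 15})
        fit = sw.fit_multinomial(df, reference="b", max_iter=60)
        assert not fit.converged
        assert "penalty" in fit.message
        fit_pen = sw.fit_multinomial(df, reference="b", penalty=1.0)
        assert fit_pen.converged

    def test_collinear_columns_named(self):
        df = simulate_multinomial(100, BETA_3CLASS, seed=6)
        df["x5"] = 2.0 * df["x1"]
        with pytest.raises(RankDeficientError) as err:
            sw.fit_multinomial(df, reference="group3")
        assert any(c in err.value.columns for c in ("x1", "x5"))

    def test_standardize_matches_raw_fit(self):
        df = simulate_multinomial(250, BETA_3CLASS, seed=7)
        df[["x1", "x2"]] *= 40.0  # uneven scales
        raw = sw.fit_multinomial(df, reference="group3")
        std = sw.fit_multinomial(df, reference="group3", standardize=True)
        assert np.max(np.abs(raw.beta - std.beta)) < 1e-6
        row = df.iloc[3][[f"x{j}" for j in range(1, 5)]]
        p_raw, _ = sw.predict_group(raw, row)
        p_std, _ = sw.predict_group(std, row)
        assert all(abs(p_raw[k] - p_std[k]) < 1e-8 for k in p_raw)

    def test_validation_errors(self):
        df = simulate_multinomial(50, BETA_3CLASS, seed=8)
        with pytest.raises(ValidationError, match="reference"):
            sw.fit_multinomial(df, reference="group9")
        df_missing = df.copy()
        df_missing.loc[0, "x1"] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            sw.fit_multinomial(df_missing, reference="group3")
        with pytest.raises(ValidationError, match="classes"):
            sw.fit_multinomial(df[df["group"] == "group1"], reference="group1")


class TestPredict:
    def test_probabilities_sum_to_one(self):
        df = simulate_multinomial(200, BETA_3CLASS, seed=9)
        fit = sw.fit_multinomial(df, reference="group3")
        for i in (0, 7, 42):
            probs, _ = sw.predict_group(fit, df.iloc[i][[f"x{j}" for j in range(1, 5)]])
            assert abs(sum(probs.values()) - 1.0) < 1e-12
            assert all(0.0 <= v <= 1.0 for v in probs.values())

    def test_extreme_covariates_stay_bounded(self):
        df = simulate_multinomial(200, BETA_3CLASS, seed=10)
        fit = sw.fit_multinomial(df, reference="group3")
        probs, _ = sw.predict_group(fit, {f"x{j}": 1e6 for j in range(1, 5)})
        assert abs(sum(probs.values()) - 1.0) < 1e-12
        assert all(np.isfinite(v) and 0.0 <= v <= 1.0 for v in probs.values())

    def test_class_mean_predicts_own_class(self):
        rng = np.random.default_rng(11)
        frames = []
        means = {"group1": (-4, 0), "group2": (4, 0), "group3": (0, 4)}
        for g, (m1, m2) in means.items():
            frames.append(pd.DataFrame({
                "x1": rng.normal(m1, 0.5, 60), "x2": rng.normal(m2, 0.5, 60),
                "group": g,
            }))
        df = pd.concat(frames, ignore_index=True)
        fit = sw.fit_multinomial(df, reference="group3", penalty=0.5)
        for g, (m1, m2) in means.items():
            _, label = sw.predict_group(fit, {"x1": m1, "x2": m2})
            assert label == g

    def test_missing_covariate_listed(self):
        df = simulate_multinomial(100, BETA_3CLASS, seed=12)
        fit = sw.fit_multinomial(df, reference="group3")
        with pytest.raises(ValidationError, match="x3"):
            sw.predict_group(fit, {"x1": 0.0, "x2": 0.0, "x4": 0.0})


class TestCoefficientTable:
    def test_table_shape_and_flags(self, covariate_frame):
        rng = np.random.default_rng(13)
        df = covariate_frame(n=60)
        # perturb so the design has full rank
        for col in [f"x{i}" for i in range(1, 24)]:
            df[col] = df[col] + rng.normal(0, 1.0, len(df)).clip(-0.9, None) \
                * (0.05 * df[col] + 0.1)
        df["x24"] = rng.integers(0, 2, len(df)).astype(float)
        df["group"] = rng.choice(["group1", "group2", "group3"], len(df))
        fit = sw.fit_multinomial(df, reference="group3", penalty=1.0)
        table = sw.coefficient_table(fit, "group1")
        assert len(table) == 25  # intercept + x1..x24
        assert table["variable"].iloc[0] == INTERCEPT
        assert list(table["variable"].iloc[1:4]) == ["x1", "x2", "x3"]
        assert (table["significant"] == (table["p_value"] < 0.05)).all()

    def test_contrast_must_differ_from_reference(self):
        df = simulate_multinomial(100, BETA_3CLASS, seed=14)
        fit = sw.fit_multinomial(df, reference="group3")
        with pytest.raises(ParameterError):
            sw.coefficient_table(fit, "group3")
        with pytest.raises(ParameterError):
            sw.coefficient_table(fit, "group7")
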