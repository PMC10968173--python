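"""Design-matrix assembly and penalised logistic fitting."""

import numpy as np
import pandas as pd
import pytest

from tbtoa.design import MODEL_SPECS, ModelSpec, assemble_features
from tbtoa.exceptions import DataError, FitError, ParameterError
from tbtoa.labels import scenario_mask
from tbtoa.regression import PenalizedLogit, aic, fit_penalized_logistic


@pytest.fixture(scope="module")
def scenario_frame(labelled_cohort):
    case, control = scenario_mask(labelled_cohort["group"].to_numpy(), "primary")
    frame = labelled_cohort[case | control].copy()
    frame["case"] = case[case | control]
    return frame.reset_index(drop=True)


class TestAssembleFeatures:
    @pytest.mark.parametrize(
        "name, n_cols, n_penalized",
        [
            ("M1", 69, 64),     # 64 TBT + age, sex, BMI, KL, JSNM
            ("M2", 69, 64),
            ("M3", 133, 128),
            ("M4", 128, 128),   # texture only
            ("M5", 136, 128),   # + 3 log-biomarkers
            ("M6", 53, 48),     # medial: 6 ROIs x 4 x 2 blocks + 5 forced
            ("M7", 53, 48),
            ("M8", 37, 32),     # central: 4 ROIs x 4 x 2 blocks + 5 forced
        ],
    )
    def test_block_arithmetic(self, scenario_frame, name, n_cols, n_penalized):
        X, y, penalized = assemble_features(scenario_frame, MODEL_SPECS[name])
        assert X.shape == (len(scenario_frame), n_cols)
        assert penalized.sum() == n_penalized
        assert len(y) == len(scenario_frame)

    def test_delta_block_is_followup_minus_baseline(self, scenario_frame):
        X, _, _ = assemble_features(scenario_frame, MODEL_SPECS["M4"])
        expected = (
            scenario_frame["tbt24_r03_milli_VF"] - scenario_frame["tbt0_r03_milli_VF"]
        ).to_numpy()
        assert X["dtbt_r03_milli_VF"].to_numpy() == pytest.approx(expected)

    def test_forced_blocks_follow_texture_blocks(self, scenario_frame):
        X, _, penalized = assemble_features(scenario_frame, MODEL_SPECS["M5"])
        assert list(X.columns[-8:]) == [
            "age", "sex", "bmi", "log_uctx2", "log_sntx1", "log_sha", "kl", "jsnm"
        ]
        assert not penalized[-8:].any()

    def test_missing_value_names_knee_and_column(self, scenario_frame):
        broken = scenario_frame.copy()
        broken.loc[broken.index[3], "bmi"] = np.nan
        with pytest.raises(DataError, match="bmi"):
            assemble_features(broken, MODEL_SPECS["M1"])

    def test_missing_response_rejected(self, labelled_cohort):
        with pytest.raises(DataError, match="case"):
            assemble_features(labelled_cohort, MODEL_SPECS["M1"])

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            ModelSpec("bad", ("TBT",), "femoral", ())


class TestAic:
    def test_hand_values(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-10.0, 3) == 26.0

    def test_monotone_in_k_at_equal_likelihood(self):
        assert aic(-50.0, 5) < aic(-50.0, 9)

    def test_negative_k_rejected(self):
        with pytest.raises(ParameterError):
            aic(-10.0, -1)


class TestPenalizedLogit:
    def test_separable_toy_reaches_training_auc_one(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        res = PenalizedLogit(y, X).fit(lambda_grid=np.array([1e-6]))
        scores = res.predict(X)
        assert (scores[y == 1].min() > scores[y == 0].max())

    def test_huge_lambda_zeroes_penalized_and_matches_forced_only_fit(self, rng):
        import statsmodels.api as sm

        n = 300
        X = rng.standard_normal((n, 5))
        z = 0.8 * X[:, 3] - 0.5 * X[:, 4]
        y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
        penalized = np.array([True, True, True, False, False])
        res = PenalizedLogit(y, X, penalized=penalized).fit(
            lambda_grid=np.array([1e6]), tol=1e-10, max_iter=20000
        )
        assert np.all(res.params[["x0", "x1", "x2"]] == 0.0)
        # forced columns behave exactly like an unpenalised logit on them alone
        ref = sm.Logit(y, sm.add_constant(X[:, 3:])).fit(disp=0)
        assert res.params["const"] == pytest.approx(ref.params[0], abs=2e-4)
        assert res.params["x3"] == pytest.approx(ref.params[1], abs=2e-4)
        assert res.params["x4"] == pytest.approx(ref.params[2], abs=2e-4)

    def test_uniform_penalty_agrees_with_liblinear(self, rng):
        from sklearn.linear_model import LogisticRegression

        n, p, lam = 400, 10, 0.02
        X = rng.standard_normal((n, p))
        beta = np.concatenate([np.array([1.0, -1.0, 0.5]), np.zeros(p - 3)])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(int)
        model = PenalizedLogit(y, X)
        res = model.fit(lambda_grid=np.array([lam]), tol=1e-10, max_iter=50000)
        mean, sd = res.standardization
        skl = LogisticRegression(
            penalty="l1", C=1.0 / (lam * n), solver="liblinear",
            intercept_scaling=100.0, tol=1e-10, max_iter=10000,
        ).fit((X - mean) / sd, y)
        ours = res.params.drop("const").to_numpy() * sd  # back to standardized scale
        assert ours == pytest.approx(skl.coef_[0], abs=5e-3)

    def test_support_recovery_concentrates_on_signal_block(self):
        # only one block of features carries signal; the AIC-selected LASSO
        # must recover that block and concentrate coefficient mass on it
        # (AIC is deliberately liberal, so a few small noise coefficients
        # survive; mass, not count, is the meaningful precision measure)
        n, p = 1500, 60
        signal = slice(40, 50)
        mass_ratios, recalls = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((n, p))
            beta = np.zeros(p)
            beta[signal] = 0.5
            y = (r.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(int)
            res = PenalizedLogit(y, X).fit()
            coefs = res.params.drop("const").to_numpy()
            mass_ratios.append(np.abs(coefs[signal]).sum() / np.abs(coefs).sum())
            recalls.append(np.mean(coefs[signal] != 0.0))
        assert np.mean(mass_ratios) >= 0.8
        assert np.mean(recalls) >= 0.9

    def test_forced_covariates_never_zeroed_along_path(self, scenario_frame):
        X, y, penalized = assemble_features(scenario_frame, MODEL_SPECS["M1"])
        model = PenalizedLogit(y, X, penalized=penalized)
        for lam in model.default_lambda_grid(n_points=4):
            res = model.fit(lambda_grid=np.array([lam]))
            forced = res.params[["age", "sex", "bmi", "kl", "jsnm"]]
            assert np.all(forced != 0.0)

    def test_fit_never_worse_than_null_deviance(self, scenario_frame):
        X, y, penalized = assemble_features(scenario_frame, MODEL_SPECS["M1"])
        res = PenalizedLogit(y, X, penalized=penalized).fit()
        p0 = y.mean()
        null_llf = len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
        assert res.llf >= null_llf

    def test_aic_selection_is_deterministic(self, scenario_frame):
        X, y, penalized = assemble_features(scenario_frame, MODEL_SPECS["M3"])
        a = PenalizedLogit(y, X, penalized=penalized).fit()
        b = PenalizedLogit(y, X, penalized=penalized).fit()
        assert a.lambda_ == b.lambda_
        pd.testing.assert_series_equal(a.params, b.params)

    def test_single_class_rejected(self):
        with pytest.raises(FitError):
            PenalizedLogit(np.zeros(10), np.random.default_rng(0).random((10, 2)))

    def test_non_finite_design_rejected(self):
        X = np.ones((6, 2))
        X[0, 0] = np.inf
        with pytest.raises(DataError):
            PenalizedLogit(np.array([0, 1] * 3), X)


class TestPrediction:
    def test_logistic_inverse_link_hand_cases(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        model = PenalizedLogit(y, X)
        res = model.fit(lambda_grid=np.array([1e-3]))
        res.params[:] = [0.0, 0.0]  # intercept 0, coefficient 0
        assert res.predict(np.array([[5.0]]))[0] == pytest.approx(0.5)
        res.params[:] = [0.0, 1.0]
        assert res.predict(np.array([[0.0]]))[0] == pytest.approx(0.5)
        assert res.predict(np.array([[np.log(3.0)]]))[0] == pytest.approx(0.75)

    def test_column_mismatch_rejected(self, scenario_frame):
        X, y, penalized = assemble_features(scenario_frame, MODEL_SPECS["M1"])
        res = PenalizedLogit(y, X, penalized=penalized).fit()
        with pytest.raises(DataError):
            res.predict(X.iloc[:, :-1])

    def test_functional_wrapper_matches_class(self, scenario_frame):
        X, y, penalized = assemble_features(scenario_frame, MODEL_SPECS["M1"])
        a = fit_penalized_logistic(X, y, penalized)
        b = PenalizedLogit(y, X, penalized=penalized).fit()
        pd.testing.assert_series_equal(a.params, b.params)

    def test_summary_mentions_selection(self, scenario_frame):
        X, y, penalized = assemble_features(scenario_frame, MODEL_SPECS["M1"])
        res = PenalizedLogit(y, X, penalized=penalized).fit()
        text = res.summary()
        assert "AIC" in text and "lambda" in text.lower()
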