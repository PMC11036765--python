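import numpy as np
import pandas as pd
import pytest
import scipy.special

from kneestrain import (EQ_PREDICTORS, PUBLISHED_MODEL, RegressionModel,
                        bivariate_screen, boxcox_transform, fit_empirical_model,
                        predict_peak_strain, znormalize)
from kneestrain.errors import InsufficientDataError, ParameterError


def eq_linear_predictor(table):
    c = PUBLISHED_MODEL.coefficients
    return (c["const"]
            + c["max_knee_flexion"] * table["max_knee_flexion"]
            + c["ankle_flexion_at_maxgrf"] * table["ankle_flexion_at_maxgrf"]
            + c["hip_flexion_at_maxgrf"] * table["hip_flexion_at_maxgrf"]
            + c["trunk_flexion_at_maxgrf"] * table["trunk_flexion_at_maxgrf"])


def posture_table(n, rng):
    return pd.DataFrame({
        "trunk_flexion_at_maxgrf": rng.uniform(5, 30, n),
        "max_knee_flexion": rng.uniform(40, 75, n),
        "ankle_flexion_at_maxgrf": rng.uniform(10, 30, n),
        "hip_flexion_at_maxgrf": rng.uniform(25, 55, n),
    })


class TestZNormalize:
    def test_hand_computed_example(self):
        assert znormalize([2.0, 4.0, 6.0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_output_moments(self, rng):
        z = znormalize(rng.uniform(1, 9, 100))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ParameterError):
            znormalize([3.0, 3.0, 3.0])

    def test_affine_invariance(self, rng):
        x = rng.uniform(0, 1, 40)
        assert znormalize(5.0 * x + 2.0) == pytest.approx(znormalize(x), abs=1e-10)


class TestBivariateScreen:
    def table_with_r(self, r, n=10, seed=0):
        """Construct x, y with empirical Pearson correlation exactly r."""
        rng = np.random.default_rng(seed)
        x = znormalize(rng.standard_normal(n))
        z = rng.standard_normal(n)
        z = z - np.polyval(np.polyfit(x, z, 1), x)      # orthogonal residual
        z = znormalize(z)
        y = r * x + np.sqrt(1 - r**2) * z
        return pd.DataFrame({"p": x, "peak_strain_pct": y})

    def test_perfect_predictor(self):
        df = pd.DataFrame({"p": np.arange(10.0), "peak_strain_pct": np.arange(10.0)})
        out = bivariate_screen(df, predictors=["p"])
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert out.loc[0, "p_value"] < 1e-9

    def test_zero_correlation_gives_p_one(self):
        df = self.table_with_r(0.0)
        out = bivariate_screen(df, predictors=["p"])
        assert out.loc[0, "pearson_r"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_moderate_correlation_not_significant_at_n10(self):
        """r = 0.6 with n = 10 misses the 0.05 threshold (t-test, 8 df)."""
        out = bivariate_screen(self.table_with_r(0.6), predictors=["p"])
        assert out.loc[0, "pearson_r"] == pytest.approx(0.6, abs=1e-12)
        assert out.loc[0, "p_value"] > 0.05

    def test_constant_predictor_flagged(self):
        df = pd.DataFrame({"p": np.ones(10), "peak_strain_pct": np.arange(10.0)})
        out = bivariate_screen(df, predictors=["p"])
        assert bool(out.loc[0, "constant"])
        assert np.isnan(out.loc[0, "pearson_r"])

    def test_needs_three_observations(self):
        df = pd.DataFrame({"p": [1.0, 2.0], "peak_strain_pct": [1.0, 2.0]})
        with pytest.raises(InsufficientDataError):
            bivariate_screen(df, predictors=["p"])


class TestBoxCox:
    def test_lambda_one_is_location_shift(self):
        x = np.array([1.0, 2.0, 5.0])
        assert np.allclose(scipy.special.boxcox(x, 1.0), x - 1.0)

    def test_lognormal_sample_gives_lambda_near_zero(self, rng):
        lam, _ = boxcox_transform(np.exp(rng.normal(0.0, 0.6, 600)))
        assert abs(lam) < 0.15

    def test_normal_sample_gives_lambda_near_one(self, rng):
        lam, _ = boxcox_transform(rng.normal(50.0, 2.0, 600))
        assert lam == pytest.approx(1.0, abs=0.5)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ParameterError):
            boxcox_transform([1.0, -2.0, 3.0])


class TestEmpiricalModelFit:
    def test_noiseless_recovery_is_exact(self, rng):
        table = posture_table(60, rng)
        table["peak_strain_pct"] = np.exp(eq_linear_predictor(table))
        model = fit_empirical_model(table, transform="log")
        for name, ref in PUBLISHED_MODEL.coefficients.items():
            assert model.coefficients[name] == pytest.approx(ref, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_single_predictor_r2_equals_squared_pearson(self, rng):
        table = posture_table(40, rng)
        table["peak_strain_pct"] = (2.0 + 0.05 * table["max_knee_flexion"]
                                    + rng.normal(0, 0.3, 40))
        model = fit_empirical_model(table, predictors=["max_knee_flexion"],
                                    transform="none")
        r = np.corrcoef(table["max_knee_flexion"], table["peak_strain_pct"])[0, 1]
        assert model.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_contributions_plus_error_total_100(self, rng):
        table = posture_table(50, rng)
        table["peak_strain_pct"] = np.exp(
            eq_linear_predictor(table) + rng.normal(0, 0.3, 50))
        model = fit_empirical_model(table, transform="boxcox")
        assert sum(model.contributions.values()) == pytest.approx(100.0, abs=0.1)
        assert set(model.contributions) == set(EQ_PREDICTORS) | {"error"}

    def test_rank_deficient_design_names_columns(self, rng):
        table = posture_table(30, rng)
        table["dup"] = 2.0 * table["max_knee_flexion"]
        table["peak_strain_pct"] = np.exp(eq_linear_predictor(table))
        with pytest.raises(ParameterError, match="collinear"):
            fit_empirical_model(table, predictors=["max_knee_flexion", "dup"],
                                transform="log")

    def test_too_few_observations(self, rng):
        table = posture_table(4, rng)
        table["peak_strain_pct"] = 1.0 + np.arange(4.0)
        with pytest.raises(InsufficientDataError):
            fit_empirical_model(table)

    def test_regression_model_invariants_enforced(self):
        with pytest.raises(ParameterError):
            RegressionModel(coefficients={"const": 0.0}, boxcox_lambda=0.0,
                            r_squared=1.5)
        with pytest.raises(ParameterError, match="100"):
            RegressionModel(coefficients={"const": 0.0}, boxcox_lambda=0.0,
                            r_squared=0.5, contributions={"a": 50.0, "error": 40.0})


class TestPredictPeakStrain:
    def test_zero_angles_give_exp_of_constant(self):
        with pytest.warns(UserWarning):      # 0 deg knee is outside the envelope
            assert predict_peak_strain(0.0, 0.0, 0.0, 0.0) == pytest.approx(
                np.exp(9.09), rel=1e-12)

    def test_hand_evaluated_posture(self):
        # knee 60, ankle 20, hip 40, trunk 10 -> ln strain ~ 0.877 -> ~2.40%
        strain = predict_peak_strain(trunk=10.0, hip=40.0, knee=60.0, ankle=20.0)
        assert strain == pytest.approx(2.404, abs=0.005)

    @pytest.mark.parametrize("angle", ["trunk", "hip", "ankle"])
    def test_flexing_trunk_hip_or_ankle_reduces_strain(self, angle):
        base = {"trunk": 10.0, "hip": 40.0, "knee": 60.0, "ankle": 20.0}
        more = dict(base)
        more[angle] += 5.0
        assert predict_peak_strain(**more) < predict_peak_strain(**base)

    def test_deeper_knee_flexion_increases_predicted_strain(self):
        """The published model's knee coefficient is positive, so its
        prediction rises with max knee flexion (noted tension with the
        soft-landing interpretation; evaluated exactly as published)."""
        base = {"trunk": 10.0, "hip": 40.0, "knee": 60.0, "ankle": 20.0}
        more = dict(base, knee=70.0)
        assert predict_peak_strain(**more) > predict_peak_strain(**base)

    def test_out_of_envelope_warns(self):
        with pytest.warns(UserWarning, match="envelope"):
            predict_peak_strain(trunk=80.0, hip=40.0, knee=60.0, ankle=20.0)

    def test_fitted_model_can_replace_published(self, rng):
        table = posture_table(60, rng)
        table["peak_strain_pct"] = np.exp(eq_linear_predictor(table))
        fitted = fit_empirical_model(table, transform="log")
        assert predict_peak_strain(10.0, 40.0, 60.0, 20.0, model=fitted) == \
            pytest.approx(predict_peak_strain(10.0, 40.0, 60.0, 20.0), rel=1e-6)
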