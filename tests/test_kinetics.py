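import numpy as np
import pandas as pd
import pytest

from thermoleaf.exceptions import InsufficientDataError, ValidationError
from thermoleaf.kinetics import (
    AsymptoticParams,
    AsymptoticStressModel,
    classify_response_shape,
    cluster_phases,
    detect_wilting_onset,
    evaluate_asymptotic,
    fit_asymptotic,
    turgor_temperature_relation,
)

CONTROL = AsymptoticParams(31.83, 4.0, 0.523)
TREATED = AsymptoticParams(82.81, 55.1, 0.0098)
GRID_8H = np.arange(0.0, 8.5, 0.5)


class TestAsymptoticFit:
    @pytest.mark.parametrize("params", [CONTROL, TREATED],
                             ids=["fast-asymptotic", "near-linear"])
    def test_noiseless_recovery_within_1e3_relative(self, params):
        y = evaluate_asymptotic(params, GRID_8H)
        res = fit_asymptotic(GRID_8H, y)
        assert res.converged
        np.testing.assert_allclose(res.theta, params.as_array(), rtol=1e-3)

    def test_model_value_at_origin(self):
        assert evaluate_asymptotic(CONTROL, 0.0) == pytest.approx(27.83)

    def test_predicted_equilibrium_is_asymptote(self):
        res = fit_asymptotic(GRID_8H, evaluate_asymptotic(CONTROL, GRID_8H))
        assert res.predicted_equilibrium == res.params.theta1
        assert res.predicted_equilibrium == pytest.approx(31.83, abs=1e-3)
        # ... and within 0.2 °C of the scenario's 32 °C ambient
        assert abs(res.predicted_equilibrium - 32.0) < 0.2

    def test_time_shift_invariance_after_reanchoring(self):
        y = evaluate_asymptotic(CONTROL, GRID_8H)
        a = fit_asymptotic(GRID_8H, y)
        shifted = GRID_8H + 3.0
        b = fit_asymptotic(shifted - shifted[0], y)
        np.testing.assert_allclose(a.theta, b.theta, rtol=1e-8)

    def test_noisy_median_asymptote_error(self):
        rng = np.random.default_rng(5)
        y0 = evaluate_asymptotic(CONTROL, GRID_8H)
        errs = [abs(fit_asymptotic(GRID_8H, y0 + rng.normal(0, 0.1, GRID_8H.size))
                    .params.theta1 - CONTROL.theta1) for _ in range(50)]
        assert np.median(errs) < 0.2

    def test_standard_errors_reported(self):
        rng = np.random.default_rng(6)
        y = evaluate_asymptotic(CONTROL, GRID_8H) + rng.normal(0, 0.1, GRID_8H.size)
        res = fit_asymptotic(GRID_8H, y)
        assert res.bse.shape == (3,) and np.all(res.bse > 0)
        diag = res.residual_diagnostics()
        assert diag["normality_pass"]

    def test_summary_mentions_key_quantities(self):
        res = fit_asymptotic(GRID_8H, evaluate_asymptotic(CONTROL, GRID_8H))
        text = res.summary()
        for token in ("theta1", "predicted equilibrium", "shape class"):
            assert token in text

    def test_input_validation(self):
        with pytest.raises(InsufficientDataError):
            AsymptoticStressModel([0.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValidationError):
            AsymptoticStressModel([0.0, -1.0, 2.0, 3.0, 4.0], np.ones(5))
        with pytest.raises(ValidationError):
            AsymptoticStressModel([0.0, 1.0, 1.0, 2.0, 3.0], np.ones(5))

    def test_from_dataframe(self):
        df = pd.DataFrame({"time_h": GRID_8H,
                           "leaf_temp": evaluate_asymptotic(CONTROL, GRID_8H)})
        res = AsymptoticStressModel.from_dataframe(df).fit()
        assert res.params.theta1 == pytest.approx(31.83, abs=1e-3)


class TestShapeClassification:
    def test_fast_rate_is_asymptotic(self):
        assert classify_response_shape(CONTROL, horizon_h=8.0) == "asymptotic"

    def test_tiny_rate_is_near_linear(self):
        assert classify_response_shape(TREATED, horizon_h=8.0) == "near_linear"

    def test_boundary_exclusive(self):
        assert classify_response_shape(
            AsymptoticParams(30.0, 5.0, 0.0625), horizon_h=8.0) == "asymptotic"

    def test_monotone_in_rate(self):
        labels = [classify_response_shape(AsymptoticParams(30.0, 5.0, t3), 8.0)
                  for t3 in np.geomspace(1e-3, 10.0, 30)]
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1 and labels[0] == "near_linear"


class TestClusterPhases:
    def test_labels_and_exclusion(self):
        out = cluster_phases([-5.0, -2.0, 0.0, 3.0, 7.0])
        assert out["phase"].tolist() == ["before_wilt", "before_wilt",
                                         "after_wilt", "after_wilt", "after_wilt"]
        assert out["included"].tolist() == [False, True, True, True, False]


class TestOnsetDetection:
    def test_constant_turgor_no_onset(self):
        s = pd.DataFrame({"time_min": np.arange(0, 600, 10.0), "turgor": 60.0})
        assert detect_wilting_onset(s).onset_min is None

    def test_step_drop_detected_at_step(self):
        t = np.arange(0, 600, 10.0)
        u = np.where(t < 300, 60.0, 5.0)
        res = detect_wilting_onset(pd.DataFrame({"time_min": t, "turgor": u}))
        assert res.onset_min == 300.0

    def test_gradual_wilt_detected_at_ramp_start(self):
        t = np.arange(0, 600, 10.0)
        u = np.clip(60.0 - 55.0 * np.clip(t - 300.0, 0, 60) / 60.0, 5.0, 60.0)
        res = detect_wilting_onset(pd.DataFrame({"time_min": t, "turgor": u}))
        assert res.onset_min == 300.0
        assert res.method == "turgor_rate"

    def test_short_series_rejected(self):
        s = pd.DataFrame({"time_min": [0.0, 10.0, 20.0], "turgor": 60.0})
        with pytest.raises(InsufficientDataError):
            detect_wilting_onset(s)

    def test_synthetic_onset_within_one_cadence(self, noiseless_run):
        series, truth = noiseless_run["series"], noiseless_run["truth"]
        cadence = noiseless_run["config"].cadence_min
        res = detect_wilting_onset(series[series["plant"] == "control"])
        assert abs(res.onset_min - truth.wilt_onset_min["control"]) <= cadence


class TestTurgorTemperatureRelation:
    def test_lowess_reproduces_exact_line(self):
        temp = np.linspace(28.5, 31.0, 40)
        turgor = 120.0 - 10.0 * temp
        rel = turgor_temperature_relation(turgor, temp)
        curve = rel.curves["all"]
        assert np.allclose(curve["turgor_smooth"],
                           120.0 - 10.0 * curve["temp"], atol=1e-6)
        assert rel.slopes["all"][0] == pytest.approx(-10.0)

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            turgor_temperature_relation([50.0] * 5, [29.0] * 5)

    def test_slope_difference_detected(self):
        rng = np.random.default_rng(3)
        temp = rng.uniform(28.5, 31.0, 80)
        grp = np.repeat(["a", "b"], 40)
        slope = np.where(grp == "a", -8.0, -20.0)
        turgor = 100.0 + slope * (temp - 28.5) + rng.normal(0, 3.0, 80)
        rel = turgor_temperature_relation(turgor, temp, grp)
        assert rel.p_value < 0.05
        assert rel.slope_difference == pytest.approx(-12.0, abs=4.0)

    def test_synthetic_day3_slopes_negative(self, noiseless_run):
        series = noiseless_run["series"]
        day3 = series[(series["time_min"] >= 2 * 1440)
                      & (series["time_min"] < 3 * 1440) & series["is_day"]]
        day3 = day3.dropna(subset=["turgor"])
        rel = turgor_temperature_relation(
            day3["turgor"], day3["leaf_temp"], day3["treatment"])
        assert all(slope < 0 for slope, _ in rel.slopes.values())
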