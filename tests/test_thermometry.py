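import numpy as np
import pandas as pd
import pytest

from thermoleaf.exceptions import ValidationError
from thermoleaf.thermometry import (
    MAX_IS_LEAF,
    MIN_IS_LEAF,
    ModeTracker,
    apical_interference_correct,
    assign_leaf_temperature,
    hourly_aggregate,
)


class TestAssignment:
    def test_transpiring_leaf_is_minimum(self):
        mode, leaf = assign_leaf_temperature(29.0, 32.5, air_temp=32.0)
        assert mode == MIN_IS_LEAF and leaf == 29.0

    def test_collapsed_distribution_switches_to_maximum(self):
        mode, leaf = assign_leaf_temperature(31.8, 32.4, air_temp=32.0)
        assert mode == MAX_IS_LEAF and leaf == 32.4

    def test_uniform_roi_same_value_either_mode(self):
        for tracker in (None, ModeTracker()):
            _, leaf = assign_leaf_temperature(30.0, 30.0, air_temp=32.0,
                                              tracker=tracker)
            assert leaf == 30.0

    def test_invalid_extremes(self):
        with pytest.raises(ValidationError):
            assign_leaf_temperature(33.0, 32.0, air_temp=32.0)

    def test_hysteresis_blocks_switch_back(self):
        tr = ModeTracker()
        mode, _ = tr.update(0.0, 31.8, 32.6, 32.0)       # switch to max
        assert mode == MAX_IS_LEAF
        mode, _ = tr.update(30.0, 29.0, 31.5, 32.0)      # reverse, too soon
        assert mode == MAX_IS_LEAF
        mode, _ = tr.update(70.0, 29.0, 31.5, 32.0)      # after hysteresis
        assert mode == MIN_IS_LEAF
        assert tr.n_switches == 2


class TestApicalCorrection:
    def test_max_mode_outlier_suppressed(self):
        values = np.concatenate([np.full(100, 30.0), [35.0]])
        robust, corrected = apical_interference_correct(values, MAX_IS_LEAF)
        assert robust == 30.0 and corrected

    def test_min_mode_symmetric(self):
        values = np.concatenate([[25.0], np.full(100, 30.0)])
        robust, corrected = apical_interference_correct(values, MIN_IS_LEAF)
        assert robust == 30.0 and corrected

    def test_clean_roi_unchanged(self):
        values = np.full(50, 30.0)
        robust, corrected = apical_interference_correct(values, MAX_IS_LEAF)
        assert robust == 30.0 and not corrected

    def test_few_pixels_fall_back_to_raw(self):
        values = np.array([30.0] * 10 + [35.0])
        robust, corrected = apical_interference_correct(values, MAX_IS_LEAF)
        assert robust == 35.0 and not corrected


def make_series(times, values, plant="p"):
    return pd.DataFrame({"time_min": times, "plant": plant, "leaf_temp": values,
                         "turgor": values})


class TestHourlyAggregate:
    schedule = [(0.0, 600.0)]  # one 10-h light period

    def test_mean_of_six_images(self):
        s = make_series(np.arange(0, 60, 10.0), [28, 28, 29, 29, 30, 30])
        out = hourly_aggregate(s, [(0.0, 60.0)])
        assert out.loc[0, "leaf_temp"] == 29.0
        assert not out.loc[0, "partial"]

    def test_constant_series_idempotent(self):
        s = make_series(np.arange(0, 600, 10.0), 30.0)
        out = hourly_aggregate(s, self.schedule)
        assert np.all(out["leaf_temp"] == 30.0)

    def test_ten_daytime_hours_give_ten_values(self):
        s = make_series(np.arange(0, 600, 10.0), 30.0)
        out = hourly_aggregate(s, self.schedule)
        assert len(out) == 10

    def test_linear_series_hits_hour_midpoint(self):
        """Exactness for linear signals under midpoint-symmetric sampling."""
        t = np.arange(5.0, 600.0, 10.0)   # 5,15,...,595: symmetric in each hour
        s = make_series(t, 20.0 + 0.01 * t)
        out = hourly_aggregate(s, self.schedule)
        mid = out["time_mid_min"].to_numpy()
        assert np.allclose(out["leaf_temp"], 20.0 + 0.01 * mid)

    def test_partial_and_empty_hours_flagged(self):
        t = np.array([0.0, 10.0, 20.0, 130.0])
        out = hourly_aggregate(make_series(t, 30.0), [(0.0, 180.0)])
        assert out.loc[0, "partial"]                     # 3 of 6 frames
        assert np.isnan(out.loc[1, "leaf_temp"]) and out.loc[1, "partial"]

    def test_cadence_must_divide_hour(self):
        with pytest.raises(ValidationError):
            hourly_aggregate(make_series([0.0], [30.0]), self.schedule,
                             cadence_min=7.0)


class TestNoiselessExtractionOracle:
    def test_leaf_temperature_matches_ground_truth_every_frame(self, noiseless_run):
        truth, series = noiseless_run["truth"], noiseless_run["series"]
        for plant in ("control", "treated"):
            got = series[series["plant"] == plant]["leaf_temp"].to_numpy()
            assert np.array_equal(got, truth.leaf_temp[plant])

    def test_air_cursor_matches_ground_truth(self, noiseless_run):
        truth, series = noiseless_run["truth"], noiseless_run["series"]
        got = series[series["plant"] == "control"]["air_temp"].to_numpy()
        assert np.array_equal(got, truth.air_temp)

    def test_switch_fires_once_for_wilting_plant_only(self, noiseless_run):
        readings = noiseless_run["readings"]
        switches = readings.groupby("plant")["n_switches"].first()
        assert switches["control"] == 1
        assert switches["treated"] == 0

    def test_delta_identity(self, noiseless_run):
        s = noiseless_run["series"]
        assert np.allclose(s["leaf_air_delta"], s["leaf_temp"] - s["air_temp"],
                           atol=1e-9)
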