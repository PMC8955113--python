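"""WMA background reference, activity detection, hourly and monthly scores."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from thermofall.activity import (
    ActivityParams,
    BackgroundModel,
    ColdModelError,
    detect_activity,
    hourly_score,
    monthly_mean_hour,
    score_capture,
    score_stream,
    update_background,
)
from thermofall.frames import ThermalFrame
from thermofall.synthetic import SceneConfig, simulate_background


class TestBackgroundModel:
    def test_wma_closed_form_on_hand_computable_window(self):
        """Values [20, 21, 22] with linear weights [1, 2, 3]:
        (20 + 42 + 66) / 6 = 21.333..."""
        model = BackgroundModel(shape=(1,), window_length=3)
        for v in (20.0, 21.0, 22.0):
            model.update(np.array([v]))
        assert model.reference[0] == pytest.approx(128.0 / 6.0)

    def test_constant_stream_fixed_point(self):
        model = BackgroundModel(shape=(2, 2), window_length=5)
        for _ in range(12):
            model.update(np.full((2, 2), 23.0))
        assert np.allclose(model.reference, 23.0)

    def test_step_change_moves_reference_monotonically(self):
        model = BackgroundModel(shape=(1,), window_length=4)
        for _ in range(4):
            model.update(np.array([20.0]))
        refs = []
        for _ in range(6):
            model.update(np.array([25.0]))
            refs.append(float(model.reference[0]))
        assert all(b >= a for a, b in zip(refs, refs[1:]))
        assert 20.0 < refs[0] < 25.0
        assert refs[-1] == pytest.approx(25.0)

    def test_rolling_window_keeps_only_last_n(self):
        model = BackgroundModel(shape=(1,), window_length=2)
        for v in (10.0, 20.0, 30.0):
            model.update(np.array([v]))
        # window holds [20, 30], weights [1, 2]
        assert model.reference[0] == pytest.approx((20 + 60) / 3)

    def test_dimension_mismatch_rejected(self):
        model = BackgroundModel(shape=(2, 2))
        with pytest.raises(ValueError):
            model.update(np.zeros((3, 3)))

    def test_masked_update_shields_foreground(self):
        model = BackgroundModel(shape=(2,), window_length=3)
        model.update(np.array([20.0, 20.0]))
        hot = np.array([35.0, 20.0])
        for _ in range(5):
            model.update(hot, active_mask=np.array([True, False]))
        assert model.reference[0] == pytest.approx(20.0)
        assert model.reference[1] == pytest.approx(20.0)

    def test_tracks_drifting_background_within_noise(self, default_config):
        """Low-pass property: on a person-free drifting stream, the
        reference stays within 3x pixel noise of the true (noise-free)
        background level."""
        cfg = default_config
        frames = simulate_background(cfg, 600)
        model = BackgroundModel(shape=(24, 32), window_length=60)
        errs = []
        for i, f in enumerate(frames):
            model.update(f.values)
            if i >= 60:
                # spatial mean estimates the clean background level
                errs.append(np.abs(model.reference - f.values.mean()).max())
        assert max(errs) < 3 * cfg.pixel_noise_sigma


class TestDetection:
    def make_warm_model(self, value=21.0, shape=(24, 32)):
        model = BackgroundModel(shape=shape, window_length=3)
        for _ in range(3):
            model.update(np.full(shape, value))
        return model

    def test_frame_equal_to_reference_is_inactive(self):
        model = self.make_warm_model()
        active, mask = detect_activity(np.full((24, 32), 21.0), model)
        assert not active and not mask.any()

    def test_blob_exceeding_threshold_detected(self):
        model = self.make_warm_model()
        frame = np.full((24, 32), 21.0)
        frame[4:6, 4:6] = 24.0  # 4 px at +3 degC
        params = ActivityParams(delta_t=1.5, min_active_pixels=2)
        active, mask = detect_activity(frame, model, params)
        assert active and mask.sum() == 4

    def test_single_hot_pixel_rejected_as_noise(self):
        model = self.make_warm_model()
        frame = np.full((24, 32), 21.0)
        frame[4, 4] = 30.0
        params = ActivityParams(delta_t=1.5, min_active_pixels=2)
        active, mask = detect_activity(frame, model, params)
        assert not active and mask.sum() == 1

    def test_negative_exceedance_does_not_count(self):
        model = self.make_warm_model()
        frame = np.full((24, 32), 15.0)  # colder than reference everywhere
        active, mask = detect_activity(frame, model)
        assert not active and not mask.any()

    def test_cold_model_raises(self):
        model = BackgroundModel(shape=(24, 32))
        with pytest.raises(ColdModelError):
            detect_activity(np.zeros((24, 32)), model)


class TestHourlyScore:
    def test_score_is_active_fraction(self):
        # 60 "frames", exactly 9 active: 15.0%
        frames = np.full((60, 4, 4), 20.0)
        frames[10:19, 1:3, 1:3] = 25.0
        score = hourly_score(
            frames, params=ActivityParams(), require_valid=False,
            window_length=5, update_every=1,
        )
        assert score == pytest.approx(100.0 * 9 / 60)

    def test_empty_hour_scores_zero(self):
        frames = np.full((40, 4, 4), 20.0)
        score = hourly_score(frames, require_valid=False, window_length=5)
        assert score == 0.0

    def test_undersized_hour_is_missing(self):
        frames = np.full((100, 4, 4), 20.0)
        assert hourly_score(frames, sensor_kind="two_d") is None

    def test_score_bounds_and_monotonicity(self):
        base = np.full((50, 4, 4), 20.0)
        scores = []
        for n_active in (0, 10, 25, 50):
            frames = base.copy()
            frames[:n_active, 1:3, 1:3] = 25.0
            # active block first, then background: model warms on frame 0
            s = hourly_score(
                frames, require_valid=False, window_length=5, update_every=1,
                masked_update=True,
            )
            scores.append(s)
            assert 0.0 <= s <= 100.0
        assert scores == sorted(scores)


class TestMonthly:
    def make_series(self, rows):
        return pd.DataFrame(
            rows, columns=["date", "hour", "room_id", "score_percent", "n_records", "valid"]
        )

    def test_mean_and_population_std(self):
        series = self.make_series(
            [
                ("2020-08-01", 10, "r", 10.0, 100, True),
                ("2020-08-02", 10, "r", 20.0, 100, True),
            ]
        )
        out = monthly_mean_hour(series, "2020-08")
        row = out[out["hour"] == 10].iloc[0]
        assert row["mean"] == pytest.approx(15.0)
        assert row["std"] == pytest.approx(5.0)

    def test_identical_days_zero_std(self):
        series = self.make_series(
            [(f"2020-08-{d:02d}", 8, "r", 12.0, 100, True) for d in range(1, 11)]
        )
        out = monthly_mean_hour(series, "2020-08")
        assert out.iloc[0]["std"] == 0.0
        assert out.iloc[0]["mean"] == pytest.approx(12.0)

    def test_missing_hours_excluded(self):
        series = self.make_series(
            [
                ("2020-08-01", 3, "r", np.nan, 10, False),
                ("2020-08-02", 3, "r", np.nan, 10, False),
                ("2020-08-01", 4, "r", 10.0, 100, True),
            ]
        )
        out = monthly_mean_hour(series, "2020-08")
        assert 3 not in set(out["hour"])
        assert 4 in set(out["hour"])

    def test_month_with_no_data_empty(self):
        series = self.make_series([("2020-08-01", 4, "r", 10.0, 100, True)])
        assert monthly_mean_hour(series, "2020-09").empty


class TestScoreCapture:
    def test_capture_split_by_hour_marks_invalid(self):
        t0 = datetime(2020, 8, 1, 0, 0, 0)
        frames = []
        # 2 fps for two hours => 7200 per hour required at default 16fps: invalid;
        # with frame_rate=2 it is exactly valid
        for i in range(2 * 7200):
            frames.append(
                ThermalFrame(t0 + timedelta(seconds=i / 2.0), np.full((24, 32), 20.0))
            )
        df = score_capture(frames, sensor_kind="two_d", frame_rate=2.0, window_length=10)
        assert len(df) == 2
        assert df["valid"].all()
        assert (df["score_percent"] == 0.0).all()

    def test_occupancy_fraction_recovered(self):
        """A scripted 10% occupancy hour is recovered within +/-2 points
        (compressed problem size: 0.5 fps)."""
        cfg = SceneConfig(seed=5)
        rate = 0.5
        n = int(3600 * rate)  # 1800 frames
        frames = simulate_background(cfg, n)
        vals = np.stack([f.values for f in frames])
        # person present for 10% of the hour, mid-hour
        start, stop = int(0.45 * n), int(0.55 * n)
        vals[start:stop, 8:16, 10:14] = cfg.body_temp
        score = hourly_score(
            vals,
            params=ActivityParams.for_kind("two_d"),
            sensor_kind="two_d",
            frame_rate=rate,
            window_length=120,
            update_every=2,
        )
        assert score == pytest.approx(10.0, abs=2.0)
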