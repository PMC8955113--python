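"""Simulator: background statistics, body rendering, scripts, 1D projection."""

import numpy as np
import pytest

from thermofall.frames import GRID_COLS, GRID_ROWS, ThermalFrame, stack_values
from thermofall.synthetic import (
    ActivityScript,
    SceneConfig,
    build_dataset,
    project_to_1d,
    render_person,
    simulate_background,
    simulate_sequence,
)


def blob_mask(values, background=21.0, margin=2.0):
    return values > background + margin


def bbox_extent(mask):
    rows, cols = np.nonzero(mask)
    return rows.max() - rows.min() + 1, cols.max() - cols.min() + 1


def centroid(mask):
    rows, cols = np.nonzero(mask)
    return rows.mean(), cols.mean()


class TestBackground:
    def test_noise_free_background_is_constant(self, quiet_config):
        frames = simulate_background(quiet_config, 10)
        for f in frames:
            assert np.all(f.values == quiet_config.t_bg_mean)

    def test_same_seed_reproduces_identical_frames(self, default_config):
        a = simulate_background(default_config, 5)
        b = simulate_background(default_config, 5)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.values, fb.values)
            assert fa.timestamp == fb.timestamp

    def test_background_statistics_match_ou_plus_noise(self, default_config):
        """Pixel deviations stay within a Gaussian-tail bound and the
        spatial mean is strongly autocorrelated (slow drift)."""
        frames = simulate_background(default_config, 1000)
        vals = stack_values(frames)
        sigma = np.hypot(default_config.bg_drift_sigma, default_config.pixel_noise_sigma)
        # ~7.7e5 Gaussian samples: P(max > 6 sigma) ~ 1e-3
        assert np.abs(vals - default_config.t_bg_mean).max() < 6 * sigma
        spatial_mean = vals.mean(axis=(1, 2))
        r = np.corrcoef(spatial_mean[:-1], spatial_mean[1:])[0, 1]
        assert r > 0.9

    def test_rejects_nonpositive_frame_count(self, default_config):
        with pytest.raises(ValueError):
            simulate_background(default_config, 0)


class TestRenderPerson:
    def make_frame(self):
        from datetime import datetime

        return ThermalFrame(datetime(2020, 8, 1), np.full((GRID_ROWS, GRID_COLS), 21.0))

    def test_upright_blob_taller_than_wide(self):
        out = render_person(self.make_frame(), "upright", (12.0, 16.0), size=6.0)
        h, w = bbox_extent(blob_mask(out.values))
        assert h > w

    def test_horizontal_blob_wider_than_tall_in_bottom_third(self):
        out = render_person(self.make_frame(), "horizontal", (20.0, 16.0), size=6.0)
        h, w = bbox_extent(blob_mask(out.values))
        assert w > h
        r, _ = centroid(blob_mask(out.values))
        assert r >= 2 * GRID_ROWS / 3

    def test_cold_body_leaves_frame_unchanged(self):
        frame = self.make_frame()
        out = render_person(frame, "upright", (12.0, 16.0), body_temp=15.0)
        assert np.array_equal(out.values, frame.values)

    def test_centroid_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            render_person(self.make_frame(), "upright", (30.0, 16.0))


class TestScripts:
    def test_absent_script_equals_background(self, default_config):
        script = ActivityScript(kind="absent", duration=1.0)
        seq = simulate_sequence(script, default_config)
        bg = simulate_background(default_config, len(seq))
        for a, b in zip(seq, bg):
            assert np.array_equal(a.values, b.values)

    def test_fall_flips_aspect_ratio(self, quiet_config):
        script = ActivityScript(kind="fall", duration=2.5, onset=0.0, fall_duration=1.0)
        seq = simulate_sequence(script, quiet_config)
        first = blob_mask(seq[0].values)
        last = blob_mask(seq[-1].values)
        h0, w0 = bbox_extent(first)
        h1, w1 = bbox_extent(last)
        assert h0 / w0 > 1
        assert h1 / w1 < 1

    def test_fall_centroid_moves_toward_floor(self, quiet_config):
        script = ActivityScript(kind="fall", duration=2.0, onset=0.2, fall_duration=0.9)
        seq = simulate_sequence(script, quiet_config)
        r0, _ = centroid(blob_mask(seq[0].values))
        r1, _ = centroid(blob_mask(seq[-1].values))
        assert r1 >= r0

    def test_walk_advances_at_scripted_speed(self, quiet_config):
        script = ActivityScript(kind="walk", duration=4.0, start_col=8.0, speed=2.0)
        seq = simulate_sequence(script, quiet_config)
        _, c0 = centroid(blob_mask(seq[0].values))
        _, c1 = centroid(blob_mask(seq[-1].values))
        assert c1 - c0 == pytest.approx(2.0 * (len(seq) - 1) / 16.0, abs=1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ActivityScript(kind="jump")

    def test_body_always_exceeds_activity_threshold(self, default_config):
        """Warm-blob pixels exceed the concurrent background by more than
        the default activity threshold, by construction."""
        script = ActivityScript(kind="walk", duration=1.0)
        seq = simulate_sequence(script, default_config)
        bg = simulate_background(default_config, len(seq))
        for a, b in zip(seq, bg):
            body = a.values != b.values
            assert body.any()
            assert np.all(a.values[body] - b.values[body] > 1.5)


class TestProjection:
    def test_uniform_frame_projects_to_uniform_records(self, quiet_config):
        frames = simulate_background(quiet_config, 16)
        recs = project_to_1d(frames, sensor_rows=[4, 10, 16, 22])
        for r in recs:
            assert r.values.shape == (32,)
            assert np.allclose(r.values, 21.0)

    def test_one_hour_at_16fps_yields_18000_records(self):
        # 3600 s of 2D capture at 16 fps, decimated to the 1D rate of 5 fps
        base = np.full((GRID_ROWS, GRID_COLS), 21.0)
        from datetime import datetime, timedelta

        t0 = datetime(2020, 8, 1)
        frames = [
            ThermalFrame(t0 + timedelta(seconds=i / 16.0), base)
            for i in range(57_600)
        ]
        recs = project_to_1d(frames, sensor_rows=[4, 10, 16, 22])
        assert len(recs) == 18_000

    def test_record_has_33_fields(self, quiet_config):
        frames = simulate_background(quiet_config, 4)
        rec = project_to_1d(frames, sensor_rows=[0, 8, 16, 23])[0]
        # timestamp + 32 measurements
        assert 1 + rec.values.size == 33

    def test_wrong_sensor_count_rejected(self, quiet_config):
        frames = simulate_background(quiet_config, 4)
        with pytest.raises(ValueError):
            project_to_1d(frames, sensor_rows=[4, 10, 16])


class TestDataset:
    def test_composition_and_balance(self):
        windows = build_dataset(n_fall=10, n_nonfall=10, n_subjects=5, seed=3)
        assert len(windows) == 20
        assert sum(w.label == "fall" for w in windows) == 10
        assert len({w.subject_id for w in windows}) == 5
        # class balance within each subject +/- 1
        for sid in {w.subject_id for w in windows}:
            falls = sum(w.label == "fall" for w in windows if w.subject_id == sid)
            nons = sum(w.label == "non_fall" for w in windows if w.subject_id == sid)
            assert abs(falls - nons) <= 1

    def test_zero_falls_allowed(self):
        windows = build_dataset(n_fall=0, n_nonfall=4, n_subjects=2, seed=0)
        assert all(w.label == "non_fall" for w in windows)

    def test_deterministic_under_seed(self):
        a = build_dataset(n_fall=2, n_nonfall=2, n_subjects=2, seed=9)
        b = build_dataset(n_fall=2, n_nonfall=2, n_subjects=2, seed=9)
        for wa, wb in zip(a, b):
            assert wa.label == wb.label and wa.subject_id == wb.subject_id
            assert np.array_equal(wa.values, wb.values)

    def test_fall_windows_end_lower_than_they_start(self):
        windows = build_dataset(n_fall=6, n_nonfall=0, n_subjects=3, seed=1)
        for w in windows:
            first = blob_mask(w.frames[0].values, margin=4.0)
            last = blob_mask(w.frames[-1].values, margin=4.0)
            if not (first.any() and last.any()):
                continue
            r0, _ = centroid(first)
            r1, _ = centroid(last)
            assert r1 >= r0 - 0.5
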