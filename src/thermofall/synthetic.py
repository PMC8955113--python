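"""Synthetic thermal scenes: drifting background, a warm human blob, scripted activities.

The simulator stands in for undeposited home/laboratory recordings. It
reproduces the statistical structure the downstream pipeline assumes:

* a person-free background whose spatial-mean temperature drifts slowly
  (mean-reverting Ornstein–Uhlenbeck process, characteristic time of the
  order of tens of minutes) plus i.i.d. per-pixel sensor noise;
* a warm elliptical body blob, always warmer than the background by more
  than the activity threshold, performing scripted activities — walking,
  sitting down, lying down, picking an object off the floor, falling;
* the acquisition-campaign composition used to validate fall detection:
  120 fall and 120 non-fall windows from 10 subjects.

Image orientation convention: row index increases downward and the floor
is the bottom rows of the grid, so "falling" moves the body centroid
toward higher row indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .frames import GRID_COLS, GRID_ROWS, LabeledWindow, SensorRecord1D, ThermalFrame

_EPOCH = datetime(2020, 8, 1, 0, 0, 0)

#: Pose names accepted by :func:`render_person`; internally each maps to a
#: tilt angle of the body's major axis measured from vertical.
POSE_ANGLES = {"upright": 0.0, "transitional": 45.0, "horizontal": 90.0}

SCRIPT_KINDS = ("walk", "sit", "lie", "pickup", "fall", "absent")

#: Activities drawn for the non-fall class; mirrors the confounders that
#: caused false alarms in deployment (coming to rest, picking up objects).
NON_FALL_KINDS = ("walk", "sit", "lie", "pickup")


@dataclass
class SceneConfig:
    """Physical and acquisition parameters of a simulated room.

    Defaults follow the deployed hardware: a 32x24 thermopile array at
    ~16 fps and four 8-pixel line sensors at ~5 fps, with an ambient
    background near 21 °C drifting on a ~20 min timescale and a body
    surface temperature near 31 °C.
    """

    grid_rows: int = GRID_ROWS
    grid_cols: int = GRID_COLS
    frame_rate_2d: float = 16.0  # Hz
    frame_rate_1d: float = 5.0  # Hz
    t_bg_mean: float = 21.0  # °C
    bg_drift_tau: float = 1200.0  # s, OU mean-reversion time
    bg_drift_sigma: float = 0.5  # °C, stationary s.d. of the drift
    pixel_noise_sigma: float = 0.3  # °C, i.i.d. per-pixel noise
    body_temp: float = 31.0  # °C, blob core temperature
    body_size: float = 6.5  # px, semi-major axis of the standing body
    threshold_margin: float = 3.0  # °C, required body-over-background margin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ValueError("grid too small")
        if self.frame_rate_2d <= 0 or self.frame_rate_1d <= 0:
            raise ValueError("frame rates must be positive")
        if self.body_temp - self.t_bg_mean <= self.threshold_margin:
            raise ValueError(
                "body_temp must exceed t_bg_mean by more than threshold_margin "
                "(the activity detector needs positive signal by construction)"
            )

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate_2d


@dataclass
class ActivityScript:
    """A scripted activity driving the body blob through a frame sequence.

    ``fall`` scripts have three phases — standing, falling, on the
    ground — controlled by ``onset`` and ``fall_duration``. ``speed`` is
    the walking speed in px/s along columns.
    """

    kind: str
    duration: float = 4.0  # s
    start_col: float = 10.0
    speed: float = 2.0  # px/s, walk
    onset: float = 1.0  # s, start of the sit/lie/pickup/fall transition
    fall_duration: float = 0.9  # s; also the transition time for sit/pickup
    lie_duration: float = 4.0  # s, deliberate lying down is slow
    direction: int = 1  # +1 falls/walks toward higher columns

    def __post_init__(self) -> None:
        if self.kind not in SCRIPT_KINDS:
            raise ValueError(f"unknown script kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "fall" and not (
            0 <= self.onset and self.onset + self.fall_duration <= self.duration
        ):
            raise ValueError("fall phases must fit inside the script duration")


# ---------------------------------------------------------------------------
# background


def simulate_background(
    config: SceneConfig,
    n_frames: int,
    rng: np.random.Generator | None = None,
    start_time: datetime = _EPOCH,
) -> list[ThermalFrame]:
    """Person-free frames: OU-drifting spatial mean plus per-pixel noise.

    The drift is a stationary Ornstein–Uhlenbeck process with time
    constant ``bg_drift_tau`` and stationary standard deviation
    ``bg_drift_sigma``, shared by all pixels; pixel noise is i.i.d.
    Gaussian with s.d. ``pixel_noise_sigma``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.dt
    alpha = math.exp(-dt / config.bg_drift_tau)
    innov_sd = config.bg_drift_sigma * math.sqrt(max(0.0, 1.0 - alpha * alpha))
    drift = np.empty(n_frames)
    b = config.bg_drift_sigma * rng.standard_normal() if config.bg_drift_sigma else 0.0
    for i in range(n_frames):
        drift[i] = b
        b = alpha * b + innov_sd * rng.standard_normal()
    shape = (n_frames, config.grid_rows, config.grid_cols)
    noise = (
        rng.standard_normal(shape) * config.pixel_noise_sigma
        if config.pixel_noise_sigma
        else np.zeros(shape)
    )
    values = config.t_bg_mean + drift[:, None, None] + noise
    return [
        ThermalFrame(start_time + timedelta(seconds=i * dt), values[i])
        for i in range(n_frames)
    ]


# ---------------------------------------------------------------------------
# body rendering


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle_deg: float,
) -> np.ndarray:
    """Boolean mask of a rotated ellipse; angle measured from vertical."""
    rows, cols = np.indices(shape)
    dr = rows - center[0]
    dc = cols - center[1]
    th = math.radians(angle_deg)
    # major axis direction: (cos th, sin th) in (row, col) coords, with
    # angle 0 = vertical (along rows) and 90 = horizontal (along cols)
    u = dr * math.cos(th) + dc * math.sin(th)
    v = -dr * math.sin(th) + dc * math.cos(th)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_person(
    frame: ThermalFrame,
    pose: str,
    centroid: tuple[float, float],
    size: float = 6.5,
    body_temp: float = 31.0,
    angle_deg: float | None = None,
) -> ThermalFrame:
    """Superimpose a warm elliptical body blob on ``frame``.

    ``pose`` selects the tilt of the body's major axis: ``upright`` is
    vertical, ``horizontal`` lies along the columns, ``transitional`` is
    the mid-fall diagonal. ``angle_deg`` overrides the pose's canonical
    angle for smooth animation. Blob pixels take
    ``max(background, body_temp)``: a body colder than the background
    leaves the frame unchanged.
    """
    if angle_deg is None:
        if pose not in POSE_ANGLES:
            raise ValueError(f"unknown pose {pose!r}")
        angle_deg = POSE_ANGLES[pose]
    shape = frame.values.shape
    r, c = centroid
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        raise ValueError(f"centroid {centroid} outside grid {shape}")
    mask = _ellipse_mask(shape, centroid, (size, 0.35 * size), angle_deg)
    out = frame.values.copy()
    out[mask] = np.maximum(out[mask], body_temp)
    return ThermalFrame(frame.timestamp, out)


# ---------------------------------------------------------------------------
# scripted sequences


def _smoothstep(x: float) -> float:
    x = min(1.0, max(0.0, x))
    return x * x * (3.0 - 2.0 * x)


def _ease_accel(x: float) -> float:
    """Quadratic ease-in: a fall accelerates from rest."""
    return min(1.0, max(0.0, x)) ** 2


@dataclass
class _BodyState:
    present: bool
    centroid: tuple[float, float] = (0.0, 0.0)
    size: float = 6.5
    angle: float = 0.0


def _body_state(script: ActivityScript, t: float, config: SceneConfig) -> _BodyState:
    """Body pose at time ``t`` seconds into the script."""
    rows = config.grid_rows
    size = config.body_size
    floor = rows - 1.0
    stand_row = floor - 0.95 * size  # feet at the floor, centroid mid-body
    ground_row = floor - 0.5 * 0.35 * size  # lying: semi-minor axis rests on floor
    col0 = script.start_col

    if script.kind == "absent":
        return _BodyState(present=False)

    if script.kind == "walk":
        # reflective walk between the grid margins, slight vertical bob
        span = config.grid_cols - 6.0
        x = (col0 - 3.0 + script.speed * t * script.direction) % (2 * span)
        col = 3.0 + (x if x <= span else 2 * span - x)
        row = stand_row + 0.4 * math.sin(2 * math.pi * 1.6 * t)
        return _BodyState(True, (row, col), size, 0.0)

    if script.kind == "fall":
        # pivot about the feet: angle 0 -> 90 with quadratic acceleration
        if t < script.onset:
            p = 0.0
        else:
            p = _ease_accel((t - script.onset) / script.fall_duration)
        ang = 90.0 * p
        th = math.radians(ang)
        lever = 0.9 * size
        row = floor - lever * math.cos(th) - 0.35 * size * (1 - p) * 0.2
        row = min(row, ground_row) if p >= 1.0 else row
        col = col0 + script.direction * lever * math.sin(th)
        col = min(max(col, 1.0), config.grid_cols - 2.0)
        return _BodyState(True, (max(0.0, row), col), size, ang)

    if script.kind == "lie":
        # the same geometry as a fall but deliberately slow
        if t < script.onset:
            p = 0.0
        else:
            p = _smoothstep((t - script.onset) / script.lie_duration)
        ang = 90.0 * p
        th = math.radians(ang)
        lever = 0.9 * size
        row = floor - lever * math.cos(th)
        col = col0 + script.direction * lever * math.sin(th)
        col = min(max(col, 1.0), config.grid_cols - 2.0)
        return _BodyState(True, (max(0.0, row), col), size, ang)

    if script.kind == "sit":
        # trunk stays near-vertical; the body shortens onto a seat
        p = 0.0 if t < script.onset else _smoothstep((t - script.onset) / 2.0)
        s = size * (1.0 - 0.45 * p)
        row = floor - 0.95 * s
        return _BodyState(True, (row, col0), s, 12.0 * p)

    if script.kind == "pickup":
        # bend down (trunk tilts, body shortens), brief hold, straighten up;
        # a voluntary stoop is much slower than a ballistic fall
        t1, hold = 1.8, 0.6
        if t < script.onset:
            p = 0.0
        elif t < script.onset + t1:
            p = _smoothstep((t - script.onset) / t1)
        elif t < script.onset + t1 + hold:
            p = 1.0
        else:
            p = 1.0 - _smoothstep((t - script.onset - t1 - hold) / t1)
        s = size * (1.0 - 0.35 * p)
        ang = 55.0 * p
        th = math.radians(ang)
        row = floor - 0.95 * s * math.cos(th)
        col = col0 + script.direction * 0.6 * s * math.sin(th)
        col = min(max(col, 1.0), config.grid_cols - 2.0)
        return _BodyState(True, (row, col), s, ang)

    raise ValueError(f"unknown script kind {script.kind!r}")


def simulate_sequence(
    script: ActivityScript,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    start_time: datetime = _EPOCH,
    body_temp: float | None = None,
) -> list[ThermalFrame]:
    """Render a full scripted activity as a 2D frame sequence.

    ``kind='absent'`` reproduces :func:`simulate_background` exactly for
    the same random state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_frames = max(1, int(round(script.duration * config.frame_rate_2d)))
    frames = simulate_background(config, n_frames, rng=rng, start_time=start_time)
    if script.kind == "absent":
        return frames
    temp = config.body_temp if body_temp is None else body_temp
    out = []
    for i, frame in enumerate(frames):
        state = _body_state(script, i * config.dt, config)
        if not state.present:
            out.append(frame)
            continue
        r = min(max(state.centroid[0], 0.0), config.grid_rows - 1.0)
        c = min(max(state.centroid[1], 0.0), config.grid_cols - 1.0)
        out.append(
            render_person(
                frame,
                pose="upright",
                centroid=(r, c),
                size=state.size,
                body_temp=temp,
                angle_deg=state.angle,
            )
        )
    return out


# ---------------------------------------------------------------------------
# 1D projection


def project_to_1d(
    frames: Sequence[ThermalFrame],
    sensor_rows: Sequence[int],
    frame_rate_2d: float = 16.0,
    frame_rate_1d: float = 5.0,
) -> list[SensorRecord1D]:
    """Project a 2D stream onto four stacked 8-pixel line sensors.

    Each selected row is averaged into 8 horizontal bins of 4 columns
    (the line sensor integrates over its wide field of view); the output
    is decimated from the 2D to the 1D frame rate. Each record carries
    33 fields: timestamp + 4 sensors x 8 pixels.
    """
    sensor_rows = list(sensor_rows)
    if len(sensor_rows) != 4 or len(set(sensor_rows)) != 4:
        raise ValueError("exactly 4 distinct sensor rows are required")
    if not frames:
        raise ValueError("frames must be non-empty")
    n_out = int(len(frames) * frame_rate_1d / frame_rate_2d)
    n_out = max(1, n_out)
    records = []
    for k in range(n_out):
        src = min(int(k * frame_rate_2d / frame_rate_1d), len(frames) - 1)
        frame = frames[src]
        vals = np.concatenate(
            [frame.values[r].reshape(8, 4).mean(axis=1) for r in sensor_rows]
        )
        records.append(SensorRecord1D(frame.timestamp, vals))
    return records


# ---------------------------------------------------------------------------
# labeled dataset


@dataclass(frozen=True)
class _Subject:
    subject_id: str
    body_temp: float
    body_size: float
    speed: float


def _make_subjects(n_subjects: int, rng: np.random.Generator) -> list[_Subject]:
    subs = []
    for i in range(n_subjects):
        subs.append(
            _Subject(
                subject_id=f"S{i:02d}",
                body_temp=float(rng.uniform(29.0, 33.0)),
                body_size=float(rng.uniform(5.5, 8.0)),
                speed=float(rng.uniform(1.5, 4.0)),
            )
        )
    return subs


def build_dataset(
    n_fall: int = 120,
    n_nonfall: int = 120,
    n_subjects: int = 10,
    seed: int = 0,
    config: SceneConfig | None = None,
    window_len: int = 24,
) -> list[LabeledWindow]:
    """Generate the labeled fall/non-fall window dataset.

    Defaults emulate the validation campaign: 120 falls and 120
    non-falls from 10 subjects, with subject-specific body temperature
    and size. Non-fall windows cycle through the confounding activities
    (walk, sit, lie, pickup). Each window is ``window_len`` frames
    (1.5 s at 16 fps) positioned over the scripted event.
    """
    if n_fall < 0 or n_nonfall < 0 or (n_fall + n_nonfall) < 1:
        raise ValueError("need at least one window")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    subjects = _make_subjects(n_subjects, rng)
    windows: list[LabeledWindow] = []

    def make_window(label: str, kind: str, sub: _Subject, idx: int) -> LabeledWindow:
        scfg = replace(cfg, body_size=sub.body_size)
        start_col = float(rng.uniform(6.0, cfg.grid_cols - 10.0))
        direction = int(rng.choice([-1, 1]))
        onset = float(rng.uniform(0.8, 1.2))
        if kind == "fall":
            script = ActivityScript(
                kind="fall",
                duration=onset + 2.5,
                start_col=start_col,
                onset=onset,
                fall_duration=float(rng.uniform(0.7, 1.1)),
                direction=direction,
            )
        elif kind == "walk":
            script = ActivityScript(
                kind="walk",
                duration=3.5,
                start_col=start_col,
                speed=sub.speed,
                direction=direction,
            )
        elif kind == "lie":
            script = ActivityScript(
                kind="lie",
                duration=onset + 5.5,
                start_col=start_col,
                onset=onset,
                lie_duration=float(rng.uniform(3.0, 5.0)),
                direction=direction,
            )
        else:  # sit, pickup
            script = ActivityScript(
                kind=kind, duration=onset + 3.0, start_col=start_col, onset=onset,
                direction=direction,
            )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        frames = simulate_sequence(
            script,
            scfg,
            rng=np.random.default_rng(sub_seed),
            body_temp=sub.body_temp,
        )
        n = len(frames)
        if kind == "walk":
            start = int(rng.integers(0, max(1, n - window_len + 1)))
        else:
            # window over the scripted transition, with a small jitter
            onset_f = int(round(script.onset * cfg.frame_rate_2d))
            start = onset_f - int(rng.integers(2, 7))
            start = min(max(0, start), max(0, n - window_len))
        sel = frames[start : start + window_len]
        return LabeledWindow(
            frames=sel,
            label=label,
            subject_id=sub.subject_id,
            kind=kind,
            window_id=f"{label}-{idx:04d}",
        )

    for i in range(n_fall):
        sub = subjects[i % n_subjects]
        windows.append(make_window("fall", "fall", sub, i))
    for i in range(n_nonfall):
        sub = subjects[i % n_subjects]
        kind = NON_FALL_KINDS[i % len(NON_FALL_KINDS)]
        windows.append(make_window("non_fall", kind, sub, i))
    return windows
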