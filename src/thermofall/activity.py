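"""Activity measurement: WMA background reference and hourly/monthly scores.

Principle: each pixel is compared against a reference ("background")
temperature; a pixel whose excess over the reference is larger than a
set threshold is active, and a frame with enough active pixels counts
as activity. Because the background itself drifts slowly (tens of
minutes) a fixed reference will not do; a weighted moving average (WMA)
with linearly increasing weights toward the present acts as a simple,
robust low-pass filter tracking it.

The hourly activity score is the percentage of active frames in that
hour; hours that fail the capture-validity rule are missing, not zero.
Monthly aggregation averages each hour-of-day over the days of the
month and reports the population standard deviation.

Two refinements over a plain WMA, both configurable:

* *masked updates* (default): currently active pixels do not enter the
  background buffer (the previous reference is used instead), so a
  stationary person does not melt into the reference;
* *decimation*: the buffer takes every ``update_every``-th frame, which
  decouples the WMA window's timescale from the frame rate.

Only positive exceedance counts: a person is warmer than the ambient
background in this use case.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from .codec import validate_capture
from .frames import ThermalFrame

DEFAULT_DELTA_T = 1.5  # °C activity threshold
DEFAULT_MIN_ACTIVE_PIXELS_2D = 2
DEFAULT_MIN_ACTIVE_PIXELS_1D = 1
DEFAULT_WINDOW_LENGTH = 600  # WMA samples
DEFAULT_UPDATE_EVERY = 16  # frames per background sample (1 Hz at 16 fps)


class ColdModelError(RuntimeError):
    """The background model has no samples yet."""


@dataclass
class ActivityParams:
    """Detection parameters: exceedance threshold and the minimum number
    of simultaneously active pixels for a frame to count (noise
    rejection; 1D bins are 4-pixel averages, hence the lower default)."""

    delta_t: float = DEFAULT_DELTA_T
    min_active_pixels: int = DEFAULT_MIN_ACTIVE_PIXELS_2D

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if self.min_active_pixels < 1:
            raise ValueError("min_active_pixels must be >= 1")

    @classmethod
    def for_kind(cls, sensor_kind: str, delta_t: float = DEFAULT_DELTA_T) -> "ActivityParams":
        mp = DEFAULT_MIN_ACTIVE_PIXELS_2D if sensor_kind == "two_d" else DEFAULT_MIN_ACTIVE_PIXELS_1D
        return cls(delta_t=delta_t, min_active_pixels=mp)


class BackgroundModel:
    """Per-pixel WMA reference temperature.

    Keeps a ring buffer of the last ``window_length`` background samples;
    the reference is the weighted mean with linearly increasing weights
    (oldest weight 1, newest weight n over the filled part)."""

    def __init__(self, shape: tuple[int, ...], window_length: int = DEFAULT_WINDOW_LENGTH):
        if window_length < 1:
            raise ValueError("window_length must be >= 1")
        self.shape = tuple(shape)
        self.window_length = window_length
        self._buffer = np.zeros((window_length,) + self.shape)
        self._count = 0
        self._pos = 0

    @property
    def n_samples(self) -> int:
        return min(self._count, self.window_length)

    @property
    def is_warm(self) -> bool:
        return self._count > 0

    @property
    def window_filled(self) -> bool:
        return self._count >= self.window_length

    @property
    def weights(self) -> np.ndarray:
        """Linear weights over the filled window, oldest to newest."""
        return np.arange(1, self.n_samples + 1, dtype=float)

    def update(self, values: np.ndarray, active_mask: np.ndarray | None = None) -> None:
        """Push one background sample. Where ``active_mask`` is set, the
        current reference is stored instead of the observed value, so
        foreground pixels do not contaminate the background."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError(f"frame shape {values.shape} != model shape {self.shape}")
        if active_mask is not None and self.is_warm:
            values = np.where(active_mask, self.reference, values)
        self._buffer[self._pos] = values
        self._pos = (self._pos + 1) % self.window_length
        self._count += 1

    @property
    def reference(self) -> np.ndarray:
        """The WMA reference: sum_i w_i x_(t-i) / sum_i w_i over the last
        ``window_length`` samples, weights increasing toward the present."""
        if not self.is_warm:
            raise ColdModelError("background model has no samples")
        n = self.n_samples
        # chronological order: oldest first
        if self._count < self.window_length:
            chron = self._buffer[:n]
        else:
            chron = np.roll(self._buffer, -self._pos, axis=0)
        w = self.weights
        return np.tensordot(w, chron, axes=(0, 0)) / w.sum()


def update_background(model: BackgroundModel, frame: ThermalFrame | np.ndarray,
                      active_mask: np.ndarray | None = None) -> BackgroundModel:
    """Functional wrapper over :meth:`BackgroundModel.update`."""
    values = frame.values if isinstance(frame, ThermalFrame) else frame
    model.update(values, active_mask=active_mask)
    return model


def detect_activity(
    frame: ThermalFrame | np.ndarray,
    model: BackgroundModel,
    params: ActivityParams | None = None,
) -> tuple[bool, np.ndarray]:
    """Pixel active iff frame - reference > delta_t (positive exceedance
    only); the frame is active iff at least ``min_active_pixels`` pixels
    are."""
    params = params or ActivityParams()
    values = frame.values if isinstance(frame, ThermalFrame) else np.asarray(frame)
    if not model.is_warm:
        raise ColdModelError("background model must be warmed up before detection")
    mask = (values - model.reference) > params.delta_t
    return bool(mask.sum() >= params.min_active_pixels), mask


def score_stream(
    values: Sequence[np.ndarray] | np.ndarray,
    params: ActivityParams | None = None,
    model: BackgroundModel | None = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    update_every: int = DEFAULT_UPDATE_EVERY,
    masked_update: bool = True,
) -> np.ndarray:
    """Per-frame activity booleans over a stream, updating the background
    online. Frames seen before the model has any sample count as
    inactive (the model warms on the first background sample)."""
    params = params or ActivityParams()
    if update_every < 1:
        raise ValueError("update_every must be >= 1")
    values = np.asarray(values, dtype=float)
    if model is None:
        model = BackgroundModel(values.shape[1:], window_length=window_length)
    active = np.zeros(len(values), dtype=bool)
    for i, frame in enumerate(values):
        mask = None
        if model.is_warm:
            active[i], mask = detect_activity(frame, model, params)
        if i % update_every == 0:
            model.update(frame, active_mask=mask if masked_update else None)
    return active


def hourly_score(
    values: Sequence[np.ndarray] | np.ndarray,
    params: ActivityParams | None = None,
    sensor_kind: str = "two_d",
    frame_rate: float | None = None,
    require_valid: bool = True,
    **stream_kwargs,
) -> float | None:
    """Activity score of one hour: 100 x active frames / total frames.

    Returns None (missing) if the hour fails the capture-validity rule —
    an interrupted capture cannot yield a score close to reality."""
    values = np.asarray(values, dtype=float)
    if require_valid and not validate_capture(
        len(values), sensor_kind, duration_h=1.0, frame_rate=frame_rate
    ):
        return None
    params = params or ActivityParams.for_kind(sensor_kind)
    active = score_stream(values, params=params, **stream_kwargs)
    return 100.0 * float(active.sum()) / len(values)


def score_capture(
    frames: Sequence[ThermalFrame],
    params: ActivityParams | None = None,
    sensor_kind: str = "two_d",
    frame_rate: float | None = None,
    room_id: str = "room",
    **stream_kwargs,
) -> pd.DataFrame:
    """Split a timestamped capture into clock hours and score each.

    Returns the activity-score series: one row per (date, hour) with
    columns ``date, hour, room_id, score_percent, n_records, valid``;
    invalid hours keep NaN scores."""
    rows = []
    by_hour: dict[tuple, list] = {}
    for fr in frames:
        key = (fr.timestamp.date(), fr.timestamp.hour)
        by_hour.setdefault(key, []).append(fr.values)
    for (date, hour), vals in sorted(by_hour.items()):
        score = hourly_score(
            np.asarray(vals), params=params, sensor_kind=sensor_kind,
            frame_rate=frame_rate, **stream_kwargs,
        )
        rows.append(
            dict(
                date=pd.Timestamp(date),
                hour=hour,
                room_id=room_id,
                score_percent=np.nan if score is None else score,
                n_records=len(vals),
                valid=score is not None,
            )
        )
    return pd.DataFrame(rows, columns=["date", "hour", "room_id", "score_percent", "n_records", "valid"])


def monthly_mean_hour(series: pd.DataFrame, month: str) -> pd.DataFrame:
    """Mean and population standard deviation of the score at each hour
    of the day over the days of ``month`` (\"YYYY-MM\"), per room.

    Missing (invalid) hours are excluded from both statistics; an hour
    with no valid day is absent from the output."""
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    period = pd.Period(month, freq="M")
    df = df[df["date"].dt.to_period("M") == period]
    df = df[df["valid"] & df["score_percent"].notna()]
    if df.empty:
        return pd.DataFrame(columns=["room_id", "hour", "mean", "std", "n_days"])
    g = df.groupby(["room_id", "hour"])["score_percent"]
    out = g.agg(mean="mean", std=lambda s: float(np.std(s, ddof=0)), n_days="count")
    return out.reset_index()
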