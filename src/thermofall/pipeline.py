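"""End-to-end orchestration of the two analyses.

One flat config governs both pipelines: activity scoring (capture ->
hourly scores -> monthly mean±std) and fall detection (dataset ->
graphs -> embedding -> forest -> CV report -> optional detection pass).
A single top-level seed fans out deterministically to every stage, and
each run writes a machine-readable provenance record (config hash,
package version, seeds).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import ActivityParams, score_capture, monthly_mean_hour
from .classify import EvalReport, FallDetector, emit_alert, evaluate
from .codec import read_capture, write_capture
from .frames import stack_values
from .graphs import window_stream
from .synthetic import SceneConfig, build_dataset


@dataclass
class RunConfig:
    """Flat run configuration; every field has the package default and
    round-trips through a ``key = value`` file."""

    seed: int = 0
    sensor_kind: str = "two_d"
    room_id: str = "room"
    frame_rate: float = 16.0  # Hz of the scored capture; validity scales with it
    # activity scoring
    delta_t: float = 1.5
    min_active_pixels: int = 2
    wma_window: int = 600
    update_every: int = 16
    # skeletonization / graphs
    fixed_threshold: float = 28.0
    min_component_px: int = 3
    max_spur_px: int = 2
    stride: int = 2
    window_len: int = 24
    hop: int = 8
    # embedding / classifier
    k: int = 30
    wl_depth: int = 2
    epochs: int = 400
    negative: int = 5
    n_estimators: int = 200
    folds: int = 5
    # dataset
    n_fall: int = 120
    n_nonfall: int = 120
    n_subjects: int = 10
    # paths
    input_path: str = ""
    output_dir: str = "out"

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if not hasattr(defaults, key):
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            cur = getattr(defaults, key)
            kwargs[key] = type(cur)(val)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(config: RunConfig, out_dir: Path, stage: str) -> None:
    rec = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "thermofall_version": __version__,
        "config": asdict(config),
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"provenance_{stage}.json").write_text(json.dumps(rec, indent=2))


def run_activity_pipeline(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a capture file hour by hour and aggregate monthly means.

    Returns (hourly score series, monthly mean±std table); both are also
    written as CSV under ``config.output_dir``.
    """
    out_dir = Path(config.output_dir)
    capture = read_capture(config.input_path, config.sensor_kind)
    if not capture.records:
        raise ValueError("capture holds no records")
    params = ActivityParams(
        delta_t=config.delta_t, min_active_pixels=config.min_active_pixels
    )
    series = score_capture(
        capture.records,
        params=params,
        sensor_kind=config.sensor_kind,
        frame_rate=config.frame_rate,
        room_id=config.room_id,
        window_length=config.wma_window,
        update_every=config.update_every,
    )
    if not series["valid"].any():
        raise ValueError("no hour passed the capture-validity rule; nothing to score")
    months = sorted(set(pd.to_datetime(series["date"]).dt.to_period("M").astype(str)))
    monthly = pd.concat(
        [monthly_mean_hour(series, m).assign(month=m) for m in months],
        ignore_index=True,
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    series.to_csv(out_dir / "scores.csv", index=False)
    monthly.to_csv(out_dir / "monthly.csv", index=False)
    write_provenance(config, out_dir, "activity")
    return series, monthly


def run_fall_pipeline(
    config: RunConfig, detect_stream=None
) -> tuple[EvalReport, FallDetector]:
    """Dataset -> graphs -> embedding -> forest -> CV report; optionally a
    detection pass over ``detect_stream`` (a frame-value sequence) whose
    alerts go to ``alerts.ndjson``."""
    out_dir = Path(config.output_dir)
    windows = build_dataset(
        n_fall=config.n_fall,
        n_nonfall=config.n_nonfall,
        n_subjects=config.n_subjects,
        seed=config.seed,
        window_len=config.window_len,
    )
    labels = [w.label for w in windows]
    graph_kwargs = dict(
        stride=config.stride,
        fixed_threshold=config.fixed_threshold,
        min_component_px=config.min_component_px,
        max_spur_px=config.max_spur_px,
    )
    from .classify import _as_graphs  # shared graph construction

    graphs = _as_graphs(windows, **graph_kwargs)
    report = evaluate(
        graphs,
        labels,
        folds=config.folds,
        seed=config.seed,
        rf_params=dict(n_estimators=config.n_estimators),
    )
    model = FallDetector(
        k=config.k,
        wl_depth=config.wl_depth,
        epochs=config.epochs,
        negative=config.negative,
        stride=config.stride,
        fixed_threshold=config.fixed_threshold,
        min_component_px=config.min_component_px,
        max_spur_px=config.max_spur_px,
        n_estimators=config.n_estimators,
        random_state=config.seed,
    )
    model.fit(graphs, labels)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    write_provenance(config, out_dir, "fall")

    if detect_stream is not None:
        frames, values = detect_stream, np.asarray([f.values for f in detect_stream])
        alert_path = out_dir / "alerts.ndjson"
        for start, g in window_stream(
            values, window_len=config.window_len, hop=config.hop, **graph_kwargs
        ):
            pred = model.predict([g])[0]
            t0 = frames[start].timestamp
            t1 = frames[min(start + config.window_len - 1, len(frames) - 1)].timestamp
            emit_alert(
                t0, t1, pred, clock=t1 + timedelta(seconds=1), log_path=alert_path
            )
    return report, model
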