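"""Core record types shared across the package.

The two sensor families produce different units of capture:

* a 32x24 thermopile array emits one temperature matrix per frame
  (~16 fps) — :class:`ThermalFrame`;
* a stack of four 8-pixel thermopile line sensors emits one 1x33 array
  per sample (~5 fps): a timestamp followed by 4 x 8 temperatures —
  :class:`SensorRecord1D`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np

#: Grid shape of the 2D thermopile array (rows, cols).
GRID_ROWS = 24
GRID_COLS = 32

#: Number of fields in a 1D record: timestamp + 4 sensors x 8 pixels.
RECORD_1D_FIELDS = 33


@dataclass
class ThermalFrame:
    """One 24x32 temperature matrix with its capture timestamp."""

    timestamp: datetime
    values: np.ndarray  # shape (24, 32), degrees Celsius

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(
                f"frame must be {GRID_ROWS}x{GRID_COLS}, got {self.values.shape}"
            )


@dataclass
class SensorRecord1D:
    """One 1x33 line-sensor record: timestamp + 32 temperatures."""

    timestamp: datetime
    values: np.ndarray  # shape (32,), degrees Celsius

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (RECORD_1D_FIELDS - 1,):
            raise ValueError(
                f"1D record must carry {RECORD_1D_FIELDS - 1} temperatures, "
                f"got shape {self.values.shape}"
            )


@dataclass
class LabeledWindow:
    """A classifier window: a short frame sequence with a fall/non-fall label."""

    frames: list[ThermalFrame]
    label: str  # "fall" or "non_fall"
    subject_id: str
    kind: str = ""  # generating activity script kind, for diagnostics
    window_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("fall", "non_fall"):
            raise ValueError(f"label must be 'fall' or 'non_fall', got {self.label!r}")

    @property
    def values(self) -> np.ndarray:
        """Stack of frame matrices, shape (n_frames, 24, 32)."""
        return np.stack([f.values for f in self.frames])


def stack_values(frames: Sequence[ThermalFrame]) -> np.ndarray:
    """Stack a frame sequence into an (n, 24, 32) array."""
    return np.stack([f.values for f in frames])
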