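"""Capture-file formats, capture-validity rules, and the trailing-zero codec.

Formats
-------
2D capture file (plain text): per frame, a header line ``# <ISO-8601
timestamp>`` followed by 24 lines of 32 space-separated temperatures
(rows=24, cols=32).

1D capture file (CSV): one record per line, 33 comma-separated fields —
an ISO-8601 timestamp followed by 32 temperatures (4 line sensors x 8
pixels).

Serialization writes temperatures as fixed-point decimals with 7
fractional digits. The sensors resolve 0.01 °C, so the last five digits
of every measurement field are zeros by construction — redundant
characters that inflate storage and transport. The codec elides exactly
those five trailing zeros per field (timestamps untouched) and restores
them on decompression, a lossless round trip. A field that does not end
in five zeros is passed through verbatim with a warning flag (prefix
``~`` in the stream) rather than corrupted.

Validity
--------
A 1 h capture is valid only if it holds at least 57,600 records (2D,
16 fps) or 18,000 records (1D, 5 fps); thresholds scale as
``frame_rate x 3600 x hours`` for non-default rates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np

from .frames import GRID_COLS, GRID_ROWS, RECORD_1D_FIELDS, SensorRecord1D, ThermalFrame

RATE_2D = 16.0  # Hz
RATE_1D = 5.0  # Hz
#: Minimum records for a valid 1 h capture, per sensor kind.
REQUIRED_RECORDS_2D = int(RATE_2D * 3600)  # 57,600
REQUIRED_RECORDS_1D = int(RATE_1D * 3600)  # 18,000

#: Fractional digits written per measurement; sensor resolution is
#: 0.01 °C, so the trailing ELIDED_ZEROS digits are always '0'.
FRAC_DIGITS = 7
ELIDED_ZEROS = 5
SENSOR_DECIMALS = FRAC_DIGITS - ELIDED_ZEROS

CODEC_VERSION = "thermofall-codec/1"
_PASSTHROUGH_MARK = "~"

_NUMERIC_RE = re.compile(r"^-?\d+\.\d+$")


class CaptureFormatError(ValueError):
    """A capture file violates its declared format."""


class CodecError(ValueError):
    """Compressed stream is malformed."""


def format_temperature(value: float) -> str:
    """Serialize one measurement: quantized to the sensor resolution,
    7 fractional digits (the last five are zeros by construction)."""
    q = round(float(value), SENSOR_DECIMALS)
    return f"{q:.{FRAC_DIGITS}f}"


def validate_capture(
    record_count: int,
    sensor_kind: str,
    duration_h: float = 1.0,
    frame_rate: float | None = None,
) -> bool:
    """Capture-validity rule: a capture represents real information only
    if records arrived without interruption, i.e. at least
    ``frame_rate x 3600 x duration_h`` records."""
    if record_count < 0:
        raise ValueError("record_count must be >= 0")
    return record_count >= required_records(sensor_kind, duration_h, frame_rate)


def required_records(
    sensor_kind: str, duration_h: float = 1.0, frame_rate: float | None = None
) -> int:
    """Queryable validity threshold (57,600/h for 2D, 18,000/h for 1D)."""
    if sensor_kind == "two_d":
        rate = RATE_2D if frame_rate is None else frame_rate
    elif sensor_kind == "one_d":
        rate = RATE_1D if frame_rate is None else frame_rate
    else:
        raise ValueError(f"unknown sensor_kind {sensor_kind!r}")
    return math.ceil(rate * 3600 * duration_h)


@dataclass
class CaptureFile:
    """A validated capture: all records of one sensor over one file."""

    sensor_kind: str  # "one_d" | "two_d"
    records: list  # SensorRecord1D or ThermalFrame

    def __post_init__(self) -> None:
        if self.sensor_kind not in ("one_d", "two_d"):
            raise ValueError(f"unknown sensor_kind {self.sensor_kind!r}")
        times = [r.timestamp for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise CaptureFormatError("timestamps must be strictly increasing")

    @property
    def start(self) -> datetime | None:
        return self.records[0].timestamp if self.records else None

    @property
    def end(self) -> datetime | None:
        return self.records[-1].timestamp if self.records else None

    def is_valid(self, duration_h: float = 1.0, frame_rate: float | None = None) -> bool:
        return validate_capture(
            len(self.records), self.sensor_kind, duration_h, frame_rate
        )


# ---------------------------------------------------------------------------
# capture read/write


def write_capture(path: str | Path, records: Sequence, sensor_kind: str) -> None:
    """Write records in the plain-text capture format for their kind."""
    path = Path(path)
    with path.open("w") as fh:
        if sensor_kind == "two_d":
            for fr in records:
                fh.write(f"# {fr.timestamp.isoformat()}\n")
                for row in fr.values:
                    fh.write(" ".join(format_temperature(v) for v in row) + "\n")
        elif sensor_kind == "one_d":
            for rec in records:
                fields = [rec.timestamp.isoformat()] + [
                    format_temperature(v) for v in rec.values
                ]
                fh.write(",".join(fields) + "\n")
        else:
            raise ValueError(f"unknown sensor_kind {sensor_kind!r}")


def read_capture(path: str | Path, sensor_kind: str) -> CaptureFile:
    """Parse and validate a capture file; malformed lines are reported
    with their line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list = []
    if sensor_kind == "one_d":
        for ln, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            fields = line.split(",")
            if len(fields) != RECORD_1D_FIELDS:
                raise CaptureFormatError(
                    f"{path}:{ln}: expected {RECORD_1D_FIELDS} fields, got {len(fields)}"
                )
            try:
                ts = datetime.fromisoformat(fields[0])
                vals = np.array([float(f) for f in fields[1:]])
            except ValueError as exc:
                raise CaptureFormatError(f"{path}:{ln}: {exc}") from exc
            records.append(SensorRecord1D(ts, vals))
    elif sensor_kind == "two_d":
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            if not lines[i].startswith("# "):
                raise CaptureFormatError(
                    f"{path}:{i + 1}: expected '# <timestamp>' frame header"
                )
            try:
                ts = datetime.fromisoformat(lines[i][2:].strip())
            except ValueError as exc:
                raise CaptureFormatError(f"{path}:{i + 1}: {exc}") from exc
            block = lines[i + 1 : i + 1 + GRID_ROWS]
            if len(block) < GRID_ROWS:
                raise CaptureFormatError(
                    f"{path}:{i + 1}: truncated frame (needs {GRID_ROWS} rows)"
                )
            rows = []
            for j, row_line in enumerate(block):
                vals = row_line.split()
                if len(vals) != GRID_COLS:
                    raise CaptureFormatError(
                        f"{path}:{i + 2 + j}: expected {GRID_COLS} values, got {len(vals)}"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise CaptureFormatError(f"{path}:{i + 2 + j}: {exc}") from exc
            records.append(ThermalFrame(ts, np.array(rows)))
            i += 1 + GRID_ROWS
    else:
        raise ValueError(f"unknown sensor_kind {sensor_kind!r}")
    return CaptureFile(sensor_kind=sensor_kind, records=records)


# ---------------------------------------------------------------------------
# trailing-zero codec


@dataclass
class CompressedRecord:
    """One record with the five redundant trailing zeros elided per
    eligible measurement field."""

    fields: list[str]
    eligible: list[bool]  # False = passed through verbatim (flagged)
    original_widths: list[int]

    @property
    def flagged(self) -> bool:
        """True if any numeric-looking field was ineligible for elision."""
        return any(
            not e and _NUMERIC_RE.match(f) for e, f in zip(self.eligible, self.fields)
        )


def _eligible(fld: str) -> bool:
    return (
        bool(_NUMERIC_RE.match(fld))
        and len(fld) > ELIDED_ZEROS
        and fld.endswith("0" * ELIDED_ZEROS)
        and "." in fld[: len(fld) - ELIDED_ZEROS]  # keep the decimal point
    )


def compress_record(fields: Sequence[str]) -> CompressedRecord:
    """Elide the five trailing zero characters of every eligible
    measurement field; timestamps and ineligible fields pass through
    verbatim (the latter flagged)."""
    out, elig, widths = [], [], []
    for fld in fields:
        widths.append(len(fld))
        if _eligible(fld):
            out.append(fld[:-ELIDED_ZEROS])
            elig.append(True)
        else:
            out.append(fld)
            elig.append(False)
    return CompressedRecord(fields=out, eligible=elig, original_widths=widths)


def decompress_record(c: CompressedRecord) -> list[str]:
    """Exact inverse of :func:`compress_record`."""
    out = []
    for fld, elig, width in zip(c.fields, c.eligible, c.original_widths):
        restored = fld + "0" * ELIDED_ZEROS if elig else fld
        if len(restored) != width:
            raise CodecError(
                f"width metadata mismatch: restored {len(restored)} != stored {width}"
            )
        out.append(restored)
    return out


def compression_rate(original_bytes: int, compressed_bytes: int) -> float:
    """1 - compressed/original, as a percentage."""
    if original_bytes <= 0:
        raise ValueError("original_bytes must be positive")
    return 100.0 * (1.0 - compressed_bytes / original_bytes)


def _split_line(line: str, sensor_kind: str) -> tuple[list[str], str]:
    if sensor_kind == "one_d":
        return line.split(","), ","
    return line.split(), " "


def compress_file(
    in_path: str | Path, out_path: str | Path, sensor_kind: str = "one_d"
) -> float:
    """Compress a capture file line by line; returns the measured
    compression rate (percent). Frame-header lines (``# ...``) pass
    through untouched; pass-through fields are marked with ``~``."""
    in_path, out_path = Path(in_path), Path(out_path)
    text = in_path.read_text()
    out_lines = [f"# {CODEC_VERSION} kind={sensor_kind} elided={ELIDED_ZEROS}"]
    for line in text.splitlines():
        if not line.strip() or line.startswith("# "):
            out_lines.append(line)
            continue
        fields, sep = _split_line(line, sensor_kind)
        comp = compress_record(fields)
        enc = [
            f if (e or not _NUMERIC_RE.match(f)) else _PASSTHROUGH_MARK + f
            for f, e in zip(comp.fields, comp.eligible)
        ]
        out_lines.append(sep.join(enc))
    out = "\n".join(out_lines) + "\n"
    out_path.write_text(out)
    original = len(text.encode())
    # rate excludes the one-line codec header, which is fixed overhead
    compressed = len(out.encode()) - len(out_lines[0].encode()) - 1
    return compression_rate(original, compressed)


def decompress_file(in_path: str | Path, out_path: str | Path) -> None:
    """Restore a file produced by :func:`compress_file`, bit-exact."""
    in_path, out_path = Path(in_path), Path(out_path)
    lines = in_path.read_text().splitlines()
    if not lines or not lines[0].startswith(f"# {CODEC_VERSION}"):
        raise CodecError("missing or unknown codec header")
    m = re.search(r"kind=(\w+)", lines[0])
    if not m:
        raise CodecError("codec header lacks sensor kind")
    sensor_kind = m.group(1)
    out_lines = []
    for line in lines[1:]:
        if not line.strip() or line.startswith("# "):
            out_lines.append(line)
            continue
        fields, sep = _split_line(line, sensor_kind)
        restored = []
        for fld in fields:
            if fld.startswith(_PASSTHROUGH_MARK):
                restored.append(fld[1:])
            elif _NUMERIC_RE.match(fld):
                restored.append(fld + "0" * ELIDED_ZEROS)
            else:
                restored.append(fld)
        out_lines.append(sep.join(restored))
    out_path.write_text("\n".join(out_lines) + "\n")
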