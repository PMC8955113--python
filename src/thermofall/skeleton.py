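"""Binary masks and single-pixel-wide skeletons from thermal frames.

Pipeline per frame: threshold (fixed, or Otsu's between-class-variance
criterion) -> morphological cleanup (3x3 closing, small-component
removal) -> Zhang–Suen two-subiteration thinning -> spur pruning.

The fixed threshold defaults to 28 °C, between typical ambient
temperatures and the apparent temperature of human skin/clothing on a
low-resolution thermopile array. Pixels outside the grid count as
background in all neighborhood operations.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, remove_small_objects

DEFAULT_THRESHOLD = 28.0  # °C
DEFAULT_MIN_COMPONENT_PX = 3
#: Spurs strictly shorter than this many pixels are pruned; 3 removes
#: spurs of up to 2 px, the scale of noise artifacts at 32x24.
DEFAULT_MAX_SPUR_PX = 3


def binarize(
    values: np.ndarray, mode: str = "fixed", fixed_threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Foreground mask: pixel is foreground iff temperature > threshold.

    ``mode='otsu'`` derives the threshold from the frame's histogram by
    maximizing between-class variance; on a constant frame the histogram
    is degenerate, so an empty mask is returned with a warning.
    """
    values = np.asarray(values, dtype=float)
    if mode == "fixed":
        if not np.isfinite(fixed_threshold):
            raise ValueError("fixed_threshold must be finite")
        thr = fixed_threshold
    elif mode == "otsu":
        if np.ptp(values) == 0:
            warnings.warn(
                "Otsu threshold undefined on a constant frame; returning empty mask",
                stacklevel=2,
            )
            return np.zeros(values.shape, dtype=bool)
        thr = float(threshold_otsu(values))
    else:
        raise ValueError(f"unknown binarization mode {mode!r}")
    return values > thr


def clean_mask(mask: np.ndarray, min_component_px: int = DEFAULT_MIN_COMPONENT_PX) -> np.ndarray:
    """Morphological cleanup: one 3x3 closing pass, then drop 8-connected
    components smaller than ``min_component_px`` pixels."""
    if min_component_px < 0:
        raise ValueError("min_component_px must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    # pad so pixels outside the grid count as background during closing
    padded = np.pad(mask, 2, constant_values=False)
    closed = closing(padded, footprint=np.ones((3, 3), dtype=bool))[2:-2, 2:-2]
    if min_component_px > 1:
        # drop components strictly smaller than min_component_px
        closed = remove_small_objects(closed, max_size=min_component_px - 1, connectivity=2)
    return closed


def _neighbors(padded: np.ndarray) -> tuple[np.ndarray, ...]:
    """The 8 neighbor planes P2..P9 (clockwise from north) of a padded mask."""
    p2 = padded[:-2, 1:-1]
    p3 = padded[:-2, 2:]
    p4 = padded[1:-1, 2:]
    p5 = padded[2:, 2:]
    p6 = padded[2:, 1:-1]
    p7 = padded[2:, :-2]
    p8 = padded[1:-1, :-2]
    p9 = padded[:-2, :-2]
    return p2, p3, p4, p5, p6, p7, p8, p9


def zhang_suen_thin(mask: np.ndarray) -> np.ndarray:
    """Zhang–Suen parallel thinning to a single-pixel-wide skeleton.

    Alternates the two sub-iterations, deleting every foreground pixel
    whose neighborhood satisfies (a) 2 <= B(P1) <= 6 neighbors,
    (b) exactly one 0->1 transition in the clockwise neighbor sequence,
    and (c)/(d) the sub-iteration's corner products are zero
    (P2*P4*P6 = 0 and P4*P6*P8 = 0 in pass one; P2*P4*P8 = 0 and
    P2*P6*P8 = 0 in pass two), until a full pass deletes nothing.
    """
    img = np.asarray(mask, dtype=bool).copy()
    if not img.any():
        return img
    changed = True
    while changed:
        changed = False
        for pass_two in (False, True):
            padded = np.pad(img, 1, constant_values=False)
            p = [x.astype(np.uint8) for x in _neighbors(padded)]
            b = np.sum(p, axis=0)
            seq = p + [p[0]]
            a = np.zeros_like(b)
            for i in range(8):
                a += (seq[i] == 0) & (seq[i + 1] == 1)
            p2, _, p4, _, p6, _, p8, _ = p
            if not pass_two:
                c1 = p2 * p4 * p6 == 0
                c2 = p4 * p6 * p8 == 0
            else:
                c1 = p2 * p4 * p8 == 0
                c2 = p2 * p6 * p8 == 0
            delete = img & (b >= 2) & (b <= 6) & (a == 1) & c1 & c2
            if delete.any():
                img &= ~delete
                changed = True
    return img


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel, 1, constant_values=False)
    return sum(x.astype(np.uint8) for x in _neighbors(padded))


def pixel_roles(skel: np.ndarray) -> dict[str, np.ndarray]:
    """Classify skeleton pixels by 8-neighbor count: endpoint (<=1),
    path (2), branch (>=3)."""
    skel = np.asarray(skel, dtype=bool)
    n = _neighbor_count(skel)
    return {
        "endpoint": skel & (n <= 1),
        "path": skel & (n == 2),
        "branch": skel & (n >= 3),
    }


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_spur(
    skel: np.ndarray, start: tuple[int, int], branch: np.ndarray
) -> list[tuple[int, int]] | None:
    """Walk from an endpoint until a branch point; return the spur pixels
    (endpoint inclusive, branch point exclusive) or None if the walk ends
    at another endpoint (an isolated segment, which pruning must keep)."""
    path = [start]
    prev = None
    cur = start
    while True:
        nbrs = [
            (cur[0] + dr, cur[1] + dc)
            for dr, dc in _OFFSETS
            if 0 <= cur[0] + dr < skel.shape[0]
            and 0 <= cur[1] + dc < skel.shape[1]
            and skel[cur[0] + dr, cur[1] + dc]
            and (cur[0] + dr, cur[1] + dc) != prev
        ]
        branch_nbrs = [n for n in nbrs if branch[n]]
        if branch_nbrs:
            return path
        if len(nbrs) != 1:
            return None  # reached another endpoint or ambiguity: keep
        prev, cur = cur, nbrs[0]
        path.append(cur)
        if len(path) > skel.size:  # safety on malformed input
            return None


def prune(skel: np.ndarray, max_spur_px: int = DEFAULT_MAX_SPUR_PX) -> np.ndarray:
    """Remove spurs — endpoint-to-branch-point branches strictly shorter
    than ``max_spur_px`` pixels — re-thinning after each removal pass
    until stable. Isolated segments (no branch point) are never removed,
    so the number of connected components is preserved. Idempotent."""
    if max_spur_px < 0:
        raise ValueError("max_spur_px must be >= 0")
    out = np.asarray(skel, dtype=bool).copy()
    if max_spur_px == 0:
        return out
    while True:
        roles = pixel_roles(out)
        endpoints = np.argwhere(roles["endpoint"])
        branch = roles["branch"]
        removed = False
        for r, c in endpoints:
            if not out[r, c]:
                continue
            spur = _trace_spur(out, (int(r), int(c)), branch)
            if spur is not None and len(spur) < max_spur_px:
                for pr, pc in spur:
                    out[pr, pc] = False
                removed = True
        if not removed:
            return out
        out = zhang_suen_thin(out)


def frame_to_skeleton(
    values: np.ndarray,
    mode: str = "fixed",
    fixed_threshold: float = DEFAULT_THRESHOLD,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
    max_spur_px: int = DEFAULT_MAX_SPUR_PX,
) -> np.ndarray:
    """Full per-frame pipeline: binarize -> clean -> thin -> prune."""
    mask = binarize(values, mode=mode, fixed_threshold=fixed_threshold)
    mask = clean_mask(mask, min_component_px=min_component_px)
    return prune(zhang_suen_thin(mask), max_spur_px=max_spur_px)


def count_components(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    return int(cc_label(mask, connectivity=2).max())
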