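"""Object detection: 8-bit conversion, global thresholding, connected components.

Lysosome-like puncta are segmented frame by frame: pixels strictly above a
global intensity threshold (default 100 on the 8-bit scale) form the
foreground, 8-connected components are the objects, and each object yields
its pixel count, binary-moment centroid and summed intensity. No size filter
is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_THRESHOLD = 100

DETECTION_COLUMNS = ["frame", "x", "y", "area_px2", "intensity_sum", "region"]

# 8-connectivity: objects touching diagonally are one component
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

__all__ = [
    "FrameStack",
    "DEFAULT_THRESHOLD",
    "DETECTION_COLUMNS",
    "to_grayscale_8bit",
    "segment_frame",
    "detect_stack",
    "summarize_counts",
]


@dataclass
class FrameStack:
    """A calibrated time-lapse grayscale stack.

    ``frames`` is a ``(T, H, W)`` array; ``pixel_size_um`` converts pixels to
    micrometres and ``frame_interval_s`` frames to seconds.
    """

    frames: np.ndarray
    pixel_size_um: float = 0.13
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def to_grayscale_8bit(frame: np.ndarray) -> np.ndarray:
    """Convert a single frame to 8-bit grayscale.

    8-bit single-channel input passes through unchanged. 16-bit input is
    rescaled by full-range division (65535 -> 255, i.e. /257) and rounded.
    3-channel input is combined with the standard luminance weights
    (0.299, 0.587, 0.114) and rounded.
    """
    frame = np.asarray(frame)
    if frame.ndim == 3:
        if frame.shape[2] != 3:
            raise ValueError(f"unsupported channel count {frame.shape[2]}")
        lum = frame[..., 0] * 0.299 + frame[..., 1] * 0.587 + frame[..., 2] * 0.114
        return np.rint(lum).astype(np.uint8)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D or 2D + 3 channels")
    if frame.dtype == np.uint8:
        return frame
    if frame.dtype == np.uint16:
        return np.rint(frame / 257.0).astype(np.uint8)
    # other numeric input: clip into the 8-bit range
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def segment_frame(
    frame: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    min_area_px2: int = 1,
    strict: bool = True,
) -> pd.DataFrame:
    """Segment one 8-bit frame into objects.

    Foreground pixels are those with intensity strictly greater than
    ``threshold`` (set ``strict=False`` for >=). Objects are 8-connected
    components; per object the pixel count, the unweighted centroid
    (mean of member pixel coordinates) and the summed intensity are
    reported, in deterministic raster-scan order of first appearance.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("segment_frame expects a 2D frame")
    fg = frame > threshold if strict else frame >= threshold
    labels, n = ndimage.label(fg, structure=_STRUCTURE_8)
    if n == 0:
        return pd.DataFrame(columns=DETECTION_COLUMNS).astype(
            {"frame": int, "x": float, "y": float, "area_px2": int, "intensity_sum": float}
        )
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(fg, labels, idx).astype(int)
    # binary-moment centroids: mean of member pixel (row, col)
    centroids = ndimage.center_of_mass(fg, labels, idx)
    centroids = np.asarray(centroids, dtype=float)  # (n, 2) as (row, col)
    sums = ndimage.sum_labels(frame.astype(float), labels, idx)
    table = pd.DataFrame(
        {
            "frame": 0,
            "x": centroids[:, 1],
            "y": centroids[:, 0],
            "area_px2": areas,
            "intensity_sum": sums,
            "region": "none",
        }
    )
    if min_area_px2 > 1:
        table = table[table["area_px2"] >= min_area_px2].reset_index(drop=True)
    return table


def detect_stack(
    stack: FrameStack,
    threshold: int = DEFAULT_THRESHOLD,
    max_frames: int | None = 50,
    min_area_px2: int = 1,
) -> pd.DataFrame:
    """Segment the first ``max_frames`` frames of a stack (``None`` = all).

    Returns the concatenated per-frame detection tables with the ``frame``
    column populated. Frames are converted to 8-bit grayscale first.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    t = stack.n_frames if max_frames is None else min(max_frames, stack.n_frames)
    parts = []
    for f in range(t):
        rows = segment_frame(to_grayscale_8bit(stack.frames[f]), threshold, min_area_px2)
        rows["frame"] = f
        parts.append(rows)
    return pd.concat(parts, ignore_index=True)


def summarize_counts(
    detections: pd.DataFrame, n_frames: int | None = None
) -> tuple[pd.Series, float]:
    """Per-frame object counts and their arithmetic mean.

    Frames in ``range(n_frames)`` with no detections count as zero; if
    ``n_frames`` is omitted it is inferred as ``max(frame) + 1``.
    """
    if len(detections) == 0:
        if not n_frames:
            return pd.Series(dtype=int), float("nan")
        counts = pd.Series(0, index=pd.RangeIndex(n_frames, name="frame"))
        return counts, 0.0
    if n_frames is None:
        n_frames = int(detections["frame"].max()) + 1
    counts = (
        detections.groupby("frame").size()
        .reindex(pd.RangeIndex(n_frames, name="frame"), fill_value=0)
    )
    return counts, float(counts.mean())
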