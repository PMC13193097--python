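"""Reading and writing the pipeline's interchange formats.

Images travel as multi-page grayscale TIFF, tables as headered CSV,
polygons as (x, y) vertex CSVs, and results/metadata as JSON. Every stage
of the pipeline can therefore run standalone on files produced by another.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import DETECTION_COLUMNS, FrameStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_detections",
    "write_detections",
    "read_tracks",
    "write_tracks",
    "read_polygon",
    "write_polygon",
    "write_mask",
    "read_mask",
    "write_json",
    "read_json",
]


def write_stack(path, stack: FrameStack) -> None:
    """Write a stack as multi-page TIFF with calibration in the description tag."""
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
    }
    tifffile.imwrite(path, stack.frames, description=json.dumps(meta))


def read_stack(
    path, pixel_size_um: float | None = None, frame_interval_s: float | None = None
) -> FrameStack:
    """Read a multi-page TIFF; calibration from the description tag unless given."""
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(
        frames=frames,
        pixel_size_um=pixel_size_um or float(meta.get("pixel_size_um", 0.13)),
        frame_interval_s=frame_interval_s or float(meta.get("frame_interval_s", 1.0)),
    )


def write_detections(path, detections: pd.DataFrame) -> None:
    cols = [c for c in DETECTION_COLUMNS if c in detections.columns]
    detections[cols].to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks(path, tracks: pd.DataFrame) -> None:
    tracks[["particle", "frame", "x", "y"]].to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_polygon(path, polygon: np.ndarray) -> None:
    pd.DataFrame(np.asarray(polygon), columns=["x", "y"]).to_csv(path, index=False)


def read_polygon(path) -> np.ndarray:
    """Read a polygon from a CSV vertex list or GeoJSON-style JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        if isinstance(obj, dict) and "coordinates" in obj:
            coords = obj["coordinates"]
            if obj.get("type") == "Polygon":
                coords = coords[0]
            return np.asarray(coords, dtype=float)
        return np.asarray(obj, dtype=float)
    df = pd.read_csv(path)
    return df[["x", "y"]].to_numpy(dtype=float)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
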