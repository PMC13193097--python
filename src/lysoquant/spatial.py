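"""Ripley's K spatial statistics for detected point patterns.

The estimator is the uncorrected area-normalized pair count

    K(r) = A / (n (n - 1)) * #{ordered pairs (i, j), i != j, d_ij <= r}

compared against the complete-spatial-randomness baseline pi r^2. No edge
correction is applied; near r comparable to the window size the estimate is
therefore biased downward relative to pi r^2, which is documented rather
than corrected (an isotropic-style correction would change the statistic).
Per-frame curves are averaged per video, and videos are aggregated per
group with normal-approximation 95% confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

DEFAULT_RADII = np.arange(1, 251, dtype=float)

__all__ = [
    "KFunctionCurve",
    "GroupKSummary",
    "DEFAULT_RADII",
    "ripley_k",
    "csr_baseline",
    "ripley_k_per_frame",
    "mean_k_over_frames",
    "group_k_summary",
]


@dataclass
class KFunctionCurve:
    """K(r) on a radius grid, with the point count and window area used."""

    radii_px: np.ndarray
    k_values: np.ndarray
    n_points: int
    window_area_px2: float
    frame: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_px": self.radii_px,
                "k": self.k_values,
                "csr_baseline": csr_baseline(self.radii_px),
            }
        )


@dataclass
class GroupKSummary:
    """Across-video mean K(r) with 95% confidence band."""

    radii_px: np.ndarray
    mean_k: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_videos: int
    group_label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_px": self.radii_px,
                "mean_k": self.mean_k,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_videos": self.n_videos,
            }
        )


def ripley_k(
    points: np.ndarray,
    radii: np.ndarray | None = None,
    window_area: float | None = None,
    frame: int | None = None,
) -> KFunctionCurve:
    """Uncorrected Ripley's K of one point pattern.

    ``window_area`` is the normalizing area A in px^2 (typically the cell
    mask pixel count). Raises on fewer than two points.
    """
    points = np.asarray(points, dtype=float)
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("insufficient points: Ripley's K needs n >= 2")
    if window_area is None or window_area <= 0:
        raise ValueError("window_area must be positive")
    if np.any(np.diff(radii) <= 0) or np.any(radii < 0):
        raise ValueError("radii must be ascending and non-negative")
    d = np.sort(pdist(points))
    # ordered pairs = 2 x unordered pairs within each radius
    pairs = 2.0 * np.searchsorted(d, radii, side="right")
    k = window_area / (n * (n - 1)) * pairs
    return KFunctionCurve(
        radii_px=radii, k_values=k, n_points=n, window_area_px2=float(window_area), frame=frame
    )


def csr_baseline(radii: np.ndarray) -> np.ndarray:
    """Theoretical K under complete spatial randomness: pi r^2."""
    radii = np.asarray(radii, dtype=float)
    return np.pi * radii**2


def ripley_k_per_frame(
    detections: pd.DataFrame,
    window_area: float,
    radii: np.ndarray | None = None,
) -> list[KFunctionCurve]:
    """K(r) for every frame of a detection table; frames with n < 2 are skipped."""
    curves = []
    skipped = 0
    for f, grp in detections.groupby("frame"):
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        if len(pts) < 2:
            skipped += 1
            continue
        curves.append(ripley_k(pts, radii, window_area, frame=int(f)))
    if skipped:
        logger.info("ripley_k_per_frame: skipped %d frame(s) with fewer than 2 points", skipped)
    return curves


def _check_grids(curves) -> np.ndarray:
    grid = curves[0].radii_px
    for c in curves[1:]:
        if not np.array_equal(c.radii_px, grid):
            raise ValueError("curves do not share a radius grid")
    return grid


def mean_k_over_frames(curves: list[KFunctionCurve]) -> KFunctionCurve:
    """Pointwise mean K(r) over a video's frames."""
    if not curves:
        raise ValueError("no curves to average")
    grid = _check_grids(curves)
    stack = np.vstack([c.k_values for c in curves])
    return KFunctionCurve(
        radii_px=grid,
        k_values=stack.mean(axis=0),
        n_points=int(round(np.mean([c.n_points for c in curves]))),
        window_area_px2=float(np.mean([c.window_area_px2 for c in curves])),
        frame=None,
    )


def group_k_summary(
    video_means: list[KFunctionCurve],
    group_label: str = "",
    z: float = 1.96,
) -> GroupKSummary:
    """Across-video mean and normal-approximation CI (mean +/- z * SD / sqrt(n))."""
    if not video_means:
        raise ValueError("no videos in group")
    grid = _check_grids(video_means)
    stack = np.vstack([c.k_values for c in video_means])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n == 1:
        warnings.warn("single video in group: CI collapses to the mean", stacklevel=2)
        half = np.zeros_like(mean)
    else:
        half = z * stack.std(axis=0, ddof=1) / np.sqrt(n)
    return GroupKSummary(
        radii_px=grid,
        mean_k=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n_videos=n,
        group_label=group_label,
    )
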