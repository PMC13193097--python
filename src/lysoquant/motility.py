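"""Trajectory linking, ensemble MSD and diffusion-exponent fitting.

Linking is a Crocker–Grier-style frame-to-frame optimal assignment: within
each frame, candidate links between active tracks and new detections are
those closer than the search range (default 9 px); among the candidates the
assignment minimizing total squared displacement wins. Tracks that miss a
frame stay "lost" and remain linkable for up to ``memory_frames`` frames
(default 5), after which they terminate. Tracks shorter than 20 detections
are discarded before MSD analysis.

The ensemble mean-squared displacement pools every displacement pair

    EMSD(tau) = < [x(t + tau) - x(t)]^2 + [y(t + tau) - y(t)]^2 >

across all retained tracks and all overlapping start times, and is fitted
to the anomalous-diffusion power law EMSD(tau) = 4 D tau^alpha by ordinary
least squares of ln(EMSD) on ln(tau). alpha < 1 is subdiffusive, alpha = 1
Brownian, alpha > 1 superdiffusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

TRACK_COLUMNS = ["particle", "frame", "x", "y"]

__all__ = [
    "LinkParams",
    "EMSDCurve",
    "DiffusionFit",
    "link_trajectories",
    "filter_tracks",
    "emsd",
    "fit_power_law",
    "regional_diffusion",
    "default_fit_lags",
]


@dataclass
class LinkParams:
    """Linker settings: per-frame search range, gap memory, length filter."""

    search_range_px: float = 9.0
    memory_frames: int = 5
    min_length: int = 20

    def __post_init__(self) -> None:
        if self.search_range_px < 0 or self.memory_frames < 0:
            raise ValueError("search range and memory must be >= 0")
        if self.min_length < 2:
            raise ValueError("min_length must be >= 2")


@dataclass
class EMSDCurve:
    """Pooled ensemble MSD per lag, in pixels^2 and (via calibration) um^2."""

    lags: np.ndarray  # lag in frames
    emsd_px2: np.ndarray
    n_pairs: np.ndarray
    frame_interval_s: float = 1.0
    pixel_size_um: float | None = None

    @property
    def lag_s(self) -> np.ndarray:
        return self.lags * self.frame_interval_s

    @property
    def emsd_um2(self) -> np.ndarray | None:
        if self.pixel_size_um is None:
            return None
        return self.emsd_px2 * self.pixel_size_um**2

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "lag_frames": self.lags,
                "lag_s": self.lag_s,
                "emsd_px2": self.emsd_px2,
                "n_pairs": self.n_pairs,
            }
        )
        if self.pixel_size_um is not None:
            out["emsd_um2"] = self.emsd_um2
        return out


@dataclass
class DiffusionFit:
    """Power-law fit of an EMSD curve: exponent, prefactor and fit quality."""

    alpha: float
    d_apparent: float  # px^2 / frame^alpha
    intercept_log: float  # fitted ln(4 D)
    r_squared: float
    fit_lag_range: tuple[int, int]
    regime: str
    alpha_stderr: float = float("nan")
    n_tracks: int = 0

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "d_apparent": self.d_apparent,
            "intercept_log": self.intercept_log,
            "r_squared": self.r_squared,
            "fit_lag_range": list(self.fit_lag_range),
            "regime": self.regime,
            "alpha_stderr": self.alpha_stderr,
            "n_tracks": self.n_tracks,
        }


# ---------------------------------------------------------------------------
# linking


class _Track:
    __slots__ = ("id", "x", "y", "last_frame", "rows")

    def __init__(self, tid: int, x: float, y: float, frame: int):
        self.id = tid
        self.x = x
        self.y = y
        self.last_frame = frame
        self.rows: list[tuple[int, int, float, float]] = [(tid, frame, x, y)]

    def extend(self, x: float, y: float, frame: int) -> None:
        self.x, self.y, self.last_frame = x, y, frame
        self.rows.append((self.id, frame, x, y))


def link_trajectories(detections: pd.DataFrame, params: LinkParams | None = None) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    Per frame, the globally optimal assignment (minimum total squared
    displacement) is found among track–detection pairs within the search
    range; detections without a link start new tracks, tracks without a
    match persist as lost for up to ``memory_frames`` frames and may be
    re-linked against their last known position (gap closing). Candidate
    pairs are split into connected components so each small assignment
    problem is solved exactly. Output columns: particle, frame, x, y.
    """
    params = params or LinkParams()
    if len(detections) == 0:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    sr = float(params.search_range_px)
    sr2 = sr * sr
    big = 1e12

    det = detections.sort_values("frame", kind="stable")
    frames = det["frame"].to_numpy(dtype=int)
    xs = det["x"].to_numpy(dtype=float)
    ys = det["y"].to_numpy(dtype=float)

    tracks: list[_Track] = []
    active: list[_Track] = []
    next_id = 0
    order = np.unique(frames)
    for f in order:
        sel = frames == f
        pts = np.column_stack([xs[sel], ys[sel]])
        # drop tracks lost for longer than the memory allows
        active = [t for t in active if f - t.last_frame <= params.memory_frames + 1]
        if not active:
            assigned = np.full(len(pts), -1, dtype=int)
        else:
            assigned = _assign(active, pts, sr, sr2, big)
        for j, ti in enumerate(assigned):
            if ti >= 0:
                active[ti].extend(pts[j, 0], pts[j, 1], int(f))
            else:
                t = _Track(next_id, pts[j, 0], pts[j, 1], int(f))
                next_id += 1
                tracks.append(t)
                active.append(t)
    rows = [r for t in tracks for r in t.rows]
    out = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return out.sort_values(["particle", "frame"], kind="stable").reset_index(drop=True)


def _assign(active: list[_Track], pts: np.ndarray, sr: float, sr2: float, big: float) -> np.ndarray:
    """Optimal track->detection assignment; returns per-detection track index or -1."""
    if len(pts) == 0:
        return np.empty(0, dtype=int)
    last = np.array([[t.x, t.y] for t in active])
    tree = cKDTree(last)
    # candidate pairs within the search range, grouped into connected
    # components so assignment matrices stay tiny
    cand = tree.query_ball_point(pts, r=sr)
    parent = list(range(len(active) + len(pts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for j, tlist in enumerate(cand):
        for ti in tlist:
            union(ti, len(active) + j)

    comp_tracks: dict[int, list[int]] = {}
    comp_dets: dict[int, list[int]] = {}
    for j, tlist in enumerate(cand):
        if not tlist:
            continue
        root = find(len(active) + j)
        comp_dets.setdefault(root, []).append(j)
        for ti in tlist:
            comp_tracks.setdefault(root, [])
            if ti not in comp_tracks[root]:
                comp_tracks[root].append(ti)

    assigned = np.full(len(pts), -1, dtype=int)
    for root, dets in comp_dets.items():
        tids = sorted(comp_tracks.get(root, []))
        dets = sorted(dets)
        m, n = len(tids), len(dets)
        cost = np.full((m + n, n + m), big)
        sub_last = last[tids]
        d2 = ((sub_last[:, None, :] - pts[dets][None, :, :]) ** 2).sum(axis=2)
        link = np.where(d2 <= sr2, d2, big)
        cost[:m, :n] = link
        # death (track unmatched) and birth (detection unmatched) at sr^2
        for i in range(m):
            cost[i, n + i] = sr2
        for j in range(n):
            cost[m + j, j] = sr2
        cost[m:, n:] = 0.0
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if i < m and j < n and cost[i, j] < big:
                assigned[dets[j]] = tids[i]
    return assigned


def filter_tracks(tracks: pd.DataFrame, min_length: int = 20) -> pd.DataFrame:
    """Keep tracks with at least ``min_length`` detections (inclusive)."""
    if len(tracks) == 0:
        return tracks.copy()
    sizes = tracks.groupby("particle")["frame"].transform("size")
    return tracks[sizes >= min_length].reset_index(drop=True)


# ---------------------------------------------------------------------------
# ensemble MSD


def emsd(
    tracks: pd.DataFrame,
    max_lag: int,
    frame_interval_s: float = 1.0,
    pixel_size_um: float | None = None,
    per_track_average: bool = False,
) -> EMSDCurve:
    """Pooled ensemble MSD over all tracks and overlapping start times.

    For each lag tau, every pair of detections (t, t + tau) present within a
    track contributes one squared displacement; frames missing inside a gap
    contribute no pairs. Lags with zero pairs are omitted. With
    ``per_track_average=True`` each track's own MSD is computed first and
    tracks are averaged with equal weight instead of pooling pairs.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if len(tracks) == 0:
        raise ValueError("no tracks given")
    lags = np.arange(1, max_lag + 1)
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    track_sums: list[np.ndarray] | None = [] if per_track_average else None
    track_counts: list[np.ndarray] | None = [] if per_track_average else None
    for _, grp in tracks.groupby("particle"):
        f = grp["frame"].to_numpy(dtype=int)
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        o = np.argsort(f)
        f, x, y = f[o], x[o], y[o]
        tsum = np.zeros(max_lag)
        tcnt = np.zeros(max_lag, dtype=int)
        for li, tau in enumerate(lags):
            target = f + tau
            present = np.isin(target, f, assume_unique=True)
            if not present.any():
                continue
            j = np.searchsorted(f, target[present])
            i = np.nonzero(present)[0]
            sq = (x[j] - x[i]) ** 2 + (y[j] - y[i]) ** 2
            tsum[li] = sq.sum()
            tcnt[li] = len(sq)
        sums += tsum
        counts += tcnt
        if per_track_average:
            track_sums.append(tsum)
            track_counts.append(tcnt)
    if counts.sum() == 0:
        raise ValueError("no usable displacement pairs at any lag")
    if per_track_average:
        ts = np.vstack(track_sums)
        tc = np.vstack(track_counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            per = np.where(tc > 0, ts / np.maximum(tc, 1), np.nan)
        vals = np.nanmean(per, axis=0)
        have = ~np.isnan(vals)
    else:
        have = counts > 0
        vals = np.full(max_lag, np.nan)
        vals[have] = sums[have] / counts[have]
    return EMSDCurve(
        lags=lags[have],
        emsd_px2=vals[have],
        n_pairs=counts[have],
        frame_interval_s=frame_interval_s,
        pixel_size_um=pixel_size_um,
    )


def default_fit_lags(max_lag: int) -> tuple[int, int]:
    """Default fit window: lags 1 .. min(20, max_lag // 2).

    Long lags pool few displacement pairs and are noisy, so the fit stays in
    the well-sampled short-lag regime unless told otherwise.
    """
    return (1, max(2, min(20, max_lag // 2)))


def fit_power_law(
    curve: EMSDCurve,
    fit_lag_range: tuple[int, int] | None = None,
    brownian_tol: float = 0.1,
    n_tracks: int = 0,
) -> DiffusionFit:
    """Fit EMSD(tau) = 4 D tau^alpha by OLS in log-log space.

    alpha is the slope of ln(EMSD) vs ln(tau); D = exp(intercept) / 4.
    The regime label uses a tolerance band of ``brownian_tol`` around
    alpha = 1. Raises when the window contains non-positive EMSD values.
    """
    if fit_lag_range is None:
        fit_lag_range = default_fit_lags(int(curve.lags.max()))
    lo, hi = fit_lag_range
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    lags = curve.lags[mask]
    vals = curve.emsd_px2[mask]
    if len(lags) < 2:
        raise ValueError("need at least 2 EMSD points in the fit range")
    bad = lags[vals <= 0]
    if len(bad):
        raise ValueError(f"non-positive EMSD at lags {bad.tolist()}; cannot take log")
    res = stats.linregress(np.log(lags), np.log(vals))
    alpha = float(res.slope)
    if alpha < 1.0 - brownian_tol:
        regime = "subdiffusive"
    elif alpha > 1.0 + brownian_tol:
        regime = "superdiffusive"
    else:
        regime = "brownian"
    return DiffusionFit(
        alpha=alpha,
        d_apparent=float(np.exp(res.intercept) / 4.0),
        intercept_log=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_lag_range=(int(lo), int(hi)),
        regime=regime,
        alpha_stderr=float(res.stderr) if res.stderr is not None else float("nan"),
        n_tracks=n_tracks,
    )


# ---------------------------------------------------------------------------
# regional analysis


def regional_diffusion(
    detections: pd.DataFrame,
    params: LinkParams | None = None,
    max_lag: int = 40,
    fit_lag_range: tuple[int, int] | None = None,
    frame_interval_s: float = 1.0,
    pixel_size_um: float | None = None,
    brownian_tol: float = 0.1,
) -> dict[str, tuple[EMSDCurve, DiffusionFit]]:
    """Link, filter, EMSD and fit independently per region.

    ``detections`` must carry region labels (see ``regions.assign_regions``);
    the whole-cell analysis uses every detection inside the cell, while the
    peripheral and perinuclear analyses use only their sub-regions. Regions
    where no track survives the length filter are simply absent from the
    result.
    """
    params = params or LinkParams()
    if "in_whole" in detections.columns:
        subsets = {
            "whole": detections[detections["in_whole"]],
            "peripheral": detections[detections["in_peripheral"]],
            "perinuclear": detections[detections["in_perinuclear"]],
        }
    elif "region" in detections.columns:
        inside = detections[detections["region"] != "none"]
        subsets = {
            "whole": inside,
            "peripheral": detections[detections["region"] == "peripheral"],
            "perinuclear": detections[detections["region"] == "perinuclear"],
        }
    else:
        raise ValueError("detections carry no region labels; run assign_regions first")

    out: dict[str, tuple[EMSDCurve, DiffusionFit]] = {}
    for name, sub in subsets.items():
        if len(sub) == 0:
            continue
        tracks = filter_tracks(link_trajectories(sub, params), params.min_length)
        if len(tracks) == 0:
            continue
        try:
            curve = emsd(tracks, max_lag, frame_interval_s, pixel_size_um)
            fit = fit_power_law(
                curve,
                fit_lag_range,
                brownian_tol,
                n_tracks=tracks["particle"].nunique(),
            )
        except ValueError:
            continue
        out[name] = (curve, fit)
    return out
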