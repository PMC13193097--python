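"""Synthetic microscopy scenes with known ground truth.

Every downstream stage of the pipeline (detection, region masks, Ripley's K,
tracking, MSD fitting) is exercised against scenes generated here: point
patterns spanning clustered / completely-spatially-random (CSR) / dispersed
regimes, trajectories spanning sub- / normal / super-diffusive motion, cell
and nucleus geometries, and rendered 8-bit image stacks.

Conventions: 0-based pixel coordinates, origin at the top-left, ``x`` is the
column index and ``y`` the row index; particle centers are continuous.
Defaults mirror the imaging conditions the pipeline targets: 0.13 um/px and
50-frame videos. All randomness flows from a single ``numpy`` generator
seeded per call; the same arguments and seed reproduce a scene bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .detection import FrameStack

DEFAULT_PIXEL_SIZE_UM = 0.13
DEFAULT_N_FRAMES = 50

__all__ = [
    "GroundTruthScene",
    "RenderParams",
    "CellGeometry",
    "simulate_point_pattern",
    "simulate_trajectories",
    "make_cell_geometry",
    "render_stack",
]


@dataclass
class CellGeometry:
    """Cell and nucleus outlines as polygons plus their raster masks.

    Polygons are ``(N, 2)`` float arrays of ``(x, y)`` vertices (closed
    implicitly); masks are boolean ``(H, W)`` rasters. ``source`` records
    whether the outline came from an annotation or from an alpha shape.
    """

    cell_polygon: np.ndarray
    nucleus_polygon: np.ndarray | None = None
    cell_mask: np.ndarray | None = None
    nucleus_mask: np.ndarray | None = None
    source: str = "annotated"

    def __post_init__(self) -> None:
        if self.nucleus_mask is not None and self.cell_mask is not None:
            if np.any(self.nucleus_mask & ~self.cell_mask):
                raise ValueError("nucleus mask must lie inside the cell mask")


@dataclass
class GroundTruthScene:
    """True particle positions per frame, with regime metadata.

    ``positions`` has columns ``frame``, ``particle``, ``x``, ``y``.
    For moving regimes particle ids are stable across frames; for static
    point patterns each frame is an independent draw.
    """

    positions: pd.DataFrame
    regime: str
    true_params: dict
    geometry: CellGeometry | None = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = 1.0
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        if len(self.positions) == 0:
            return int(self.true_params.get("n_frames", 0))
        return int(self.positions["frame"].max()) + 1

    def frame_points(self, frame: int) -> np.ndarray:
        sel = self.positions[self.positions["frame"] == frame]
        return sel[["x", "y"]].to_numpy(dtype=float)


@dataclass
class RenderParams:
    """How a scene is rasterized into an 8-bit stack.

    The defaults keep rendered spots recoverable by the default detection
    threshold of 100: peaks sit well above it, and background plus three
    noise standard deviations stays below it.
    """

    spot_sigma_px: float = 1.5
    peak_intensity: float = 180.0
    background_level: float = 20.0
    noise_sd: float = 5.0
    image_shape: tuple[int, int] = (256, 256)
    detection_threshold: float = 100.0

    def __post_init__(self) -> None:
        if not self.peak_intensity > self.detection_threshold:
            raise ValueError("peak_intensity must exceed the detection threshold")
        if not self.background_level + 3.0 * self.noise_sd < self.detection_threshold:
            raise ValueError(
                "background_level + 3*noise_sd must stay below the detection threshold"
            )


# ---------------------------------------------------------------------------
# windows


def _as_polygon(window) -> Polygon:
    """Accept a shapely polygon, an (xmax, ymax) pair, or an (x0, y0, x1, y1) box."""
    if isinstance(window, Polygon):
        poly = window
    elif np.ndim(window) == 2:
        poly = Polygon(np.asarray(window, dtype=float))
    else:
        vals = tuple(float(v) for v in np.atleast_1d(window))
        if len(vals) == 2:
            x1, y1 = vals
            x0 = y0 = 0.0
        elif len(vals) == 4:
            x0, y0, x1, y1 = vals
        else:
            raise ValueError("window must be a polygon, (W, H), or (x0, y0, x1, y1)")
        poly = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    if poly.area <= 0:
        raise ValueError("window area must be positive")
    return poly


def _sample_uniform(rng: np.random.Generator, poly: Polygon, n: int) -> np.ndarray:
    """Uniform points in a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    # acceptance ratio is area/bbox-area; batch accordingly
    ratio = max(poly.area / ((x1 - x0) * (y1 - y0)), 1e-3)
    while filled < n:
        m = max(int((n - filled) / ratio * 1.5), 16)
        pts = rng.uniform((x0, y0), (x1, y1), size=(m, 2))
        keep = _contains(poly, pts)
        pts = pts[keep]
        take = min(len(pts), n - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    return out


def _contains(poly: Polygon, pts: np.ndarray) -> np.ndarray:
    from shapely import contains_xy

    return contains_xy(poly, pts[:, 0], pts[:, 1])


# ---------------------------------------------------------------------------
# point patterns


def simulate_point_pattern(
    kind: str,
    *,
    window,
    n_points: int | None = None,
    intensity: float | None = None,
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int | None = None,
    cluster_parents: int = 10,
    cluster_sd_px: float = 5.0,
    hardcore_radius_px: float = 10.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s: float = 1.0,
    max_retries: int = 200,
) -> GroundTruthScene:
    """Draw independent per-frame point patterns inside a window.

    Parameters
    ----------
    kind
        ``"csr"`` (uniform; fixed ``n_points`` by default, Poisson counts if
        ``intensity`` is given instead), ``"clustered"`` (Thomas-type
        parent–offspring process: uniform parents, Gaussian-scattered
        offspring clipped to the window), or ``"dispersed"`` (hard-core
        thinning: sequential placement rejecting points closer than
        ``hardcore_radius_px``).
    window
        Shapely polygon, ``(W, H)`` rectangle, or ``(x0, y0, x1, y1)`` box.
    """
    poly = _as_polygon(window)
    rng = np.random.default_rng(seed)
    if kind not in {"csr", "clustered", "dispersed"}:
        raise ValueError(f"unknown pattern kind {kind!r}")
    if kind != "clustered" and n_points is None and intensity is None:
        raise ValueError("give n_points or intensity")

    rows: list[pd.DataFrame] = []
    for f in range(n_frames):
        if kind == "csr":
            n = int(rng.poisson(intensity * poly.area)) if n_points is None else n_points
            pts = _sample_uniform(rng, poly, n)
        elif kind == "clustered":
            parents = _sample_uniform(rng, poly, cluster_parents)
            if n_points is None:
                counts = rng.poisson(5.0, size=cluster_parents)
            else:
                # split n_points as evenly as possible over parents
                counts = np.full(cluster_parents, n_points // cluster_parents)
                counts[: n_points % cluster_parents] += 1
            offs = []
            for p, c in zip(parents, counts):
                got = 0
                while got < c:
                    cand = p + rng.normal(0.0, cluster_sd_px, size=(c - got, 2))
                    cand = cand[_contains(poly, cand)]
                    offs.append(cand)
                    got += len(cand)
            pts = np.vstack(offs)[: int(np.sum(counts))] if offs else np.empty((0, 2))
        else:  # dispersed
            pts = _hardcore_pattern(rng, poly, n_points, hardcore_radius_px, max_retries)
        rows.append(
            pd.DataFrame(
                {
                    "frame": f,
                    "particle": np.arange(len(pts)),
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                }
            )
        )
    positions = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["frame", "particle", "x", "y"]
    )
    params = {
        "n_points": n_points,
        "intensity": intensity,
        "cluster_parents": cluster_parents,
        "cluster_sd_px": cluster_sd_px,
        "hardcore_radius_px": hardcore_radius_px,
        "window_area_px2": poly.area,
        "n_frames": n_frames,
    }
    return GroundTruthScene(
        positions=positions,
        regime=kind,
        true_params=params,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        seed=seed,
    )


def _hardcore_pattern(
    rng: np.random.Generator,
    poly: Polygon,
    n: int,
    h: float,
    max_retries: int,
) -> np.ndarray:
    """Sequential hard-core (dart-throwing) placement; errors when packing fails."""
    from scipy.spatial import cKDTree

    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = _sample_uniform(rng, poly, 1)[0]
        if pts:
            tree = cKDTree(np.asarray(pts))
            if tree.query_ball_point(cand, r=h):
                tries += 1
                if tries > max_retries * n:
                    raise RuntimeError(
                        f"hard-core radius {h} infeasible for n={n} in this window"
                    )
                continue
        pts.append(cand)
    return np.asarray(pts) if pts else np.empty((0, 2))


# ---------------------------------------------------------------------------
# trajectories


def simulate_trajectories(
    regime: str,
    *,
    n_particles: int,
    n_frames: int,
    window,
    d: float = 0.25,
    velocity: float | tuple[float, float] = 0.0,
    corral_radius_px: float = 5.0,
    seed: int | None = None,
    start_positions: np.ndarray | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s: float = 1.0,
) -> GroundTruthScene:
    """Simulate 2D trajectories with stable particle identities.

    ``brownian``: per-axis increments are Normal(0, 2*D*dt) with dt = one
    frame, so the ensemble MSD is 4*D*tau. ``confined``: the same increments
    reflected at a circular corral of radius ``corral_radius_px`` centred on
    each particle's start. ``directed``: constant drift plus Brownian noise;
    a scalar ``velocity`` gives each particle a random fixed heading of that
    speed, a 2-vector gives all particles the same drift. Particles reflect
    at the window edges rather than wrapping, so the linker never sees a
    spurious jump across the field of view.
    """
    if regime not in {"brownian", "confined", "directed"}:
        raise ValueError(f"unknown motion regime {regime!r}")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if d < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if regime == "confined" and corral_radius_px <= 0:
        raise ValueError("corral radius must be positive")
    poly = _as_polygon(window)
    x0, y0, x1, y1 = poly.bounds
    rng = np.random.default_rng(seed)

    speed = float(np.hypot(*velocity)) if np.ndim(velocity) else float(velocity)
    if speed > min(x1 - x0, y1 - y0):
        raise ValueError("per-frame velocity exceeds the window size")

    if start_positions is None:
        starts = _sample_uniform(rng, poly, n_particles)
    else:
        starts = np.asarray(start_positions, dtype=float)
        if starts.shape != (n_particles, 2):
            raise ValueError("start_positions must have shape (n_particles, 2)")

    if regime == "directed":
        if np.ndim(velocity):
            drift = np.tile(np.asarray(velocity, dtype=float), (n_particles, 1))
        else:
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n_particles)
            drift = speed * np.column_stack([np.cos(theta), np.sin(theta)])
    else:
        drift = np.zeros((n_particles, 2))

    sigma = float(np.sqrt(2.0 * d))
    pos = starts.copy()
    traj = np.empty((n_frames, n_particles, 2))
    traj[0] = pos
    for f in range(1, n_frames):
        step = drift + (rng.normal(0.0, sigma, size=(n_particles, 2)) if sigma > 0 else 0.0)
        pos = pos + step
        if regime == "confined":
            pos = _reflect_circle(pos, starts, corral_radius_px)
        pos[:, 0] = _reflect_interval(pos[:, 0], x0, x1)
        pos[:, 1] = _reflect_interval(pos[:, 1], y0, y1)
        traj[f] = pos

    frames = np.repeat(np.arange(n_frames), n_particles)
    particles = np.tile(np.arange(n_particles), n_frames)
    positions = pd.DataFrame(
        {
            "frame": frames,
            "particle": particles,
            "x": traj[:, :, 0].ravel(),
            "y": traj[:, :, 1].ravel(),
        }
    )
    params = {
        "d_px2_per_frame": d,
        "velocity_px_per_frame": speed,
        "corral_radius_px": corral_radius_px if regime == "confined" else None,
        "n_particles": n_particles,
        "n_frames": n_frames,
        "window_area_px2": poly.area,
    }
    return GroundTruthScene(
        positions=positions,
        regime=regime,
        true_params=params,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        seed=seed,
    )


def _reflect_interval(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mirror-reflect values into [lo, hi]."""
    span = hi - lo
    v = np.mod(v - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo


def _reflect_circle(pos: np.ndarray, centers: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect positions back inside per-particle circular corrals."""
    out = pos.copy()
    for _ in range(8):  # repeated reflection converges for any finite step
        delta = out - centers
        r = np.hypot(delta[:, 0], delta[:, 1])
        outside = r > radius
        if not np.any(outside):
            break
        scale = (2.0 * radius - r[outside]) / r[outside]
        # a step more than 2R past the centre would reflect to negative radius;
        # clamp to the boundary in that pathological case
        scale = np.clip(scale, 0.0, None)
        out[outside] = centers[outside] + delta[outside] * scale[:, None]
    return out


# ---------------------------------------------------------------------------
# cell geometry


def make_cell_geometry(
    cell_area_um2: float = 900.0,
    nucleus_fraction: float = 0.15,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: str = "disk",
    seed: int | None = None,
    n_vertices: int = 256,
    image_shape: tuple[int, int] | None = None,
    blob_amplitude: float = 0.08,
    blob_modes: Sequence[int] = (2, 3, 5),
) -> CellGeometry:
    """Build a cell polygon of a target area with a concentric nucleus.

    ``disk`` gives a circle; ``blob`` perturbs the disk radius with a few
    low-order Fourier modes (amplitude ``blob_amplitude`` per mode) and then
    rescales so the polygon area still matches ``cell_area_um2``. The
    realized pixel-mask area stays within 2% of the request for cells at
    realistic scale (hundreds of um^2 at ~0.13 um/px).
    """
    if not 0.0 < nucleus_fraction < 1.0:
        raise ValueError("nucleus_fraction must be in (0, 1)")
    if cell_area_um2 <= 0:
        raise ValueError("cell_area_um2 must be positive")
    rng = np.random.default_rng(seed)
    r_px = np.sqrt(cell_area_um2 / np.pi) / pixel_size_um
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    if shape == "disk":
        radius = np.full(n_vertices, r_px)
    elif shape == "blob":
        radius = np.full(n_vertices, r_px)
        for k in blob_modes:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            radius = radius * (1.0 + blob_amplitude * np.cos(k * theta + phase))
    else:
        raise ValueError(f"unknown shape {shape!r}")

    margin = 1.25
    if image_shape is None:
        side = int(np.ceil(2.0 * radius.max() * margin))
        image_shape = (side, side)
    cy, cx = image_shape[0] / 2.0, image_shape[1] / 2.0

    def polygon_of(rad: np.ndarray) -> np.ndarray:
        return np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)])

    # rescale so the polygon area matches the requested area exactly
    target_px2 = cell_area_um2 / pixel_size_um**2
    area = Polygon(polygon_of(radius)).area
    radius = radius * np.sqrt(target_px2 / area)
    cell_polygon = polygon_of(radius)
    nucleus_polygon = polygon_of(np.full(n_vertices, np.sqrt(nucleus_fraction) * r_px))

    from skimage.draw import polygon2mask

    cell_mask = polygon2mask(image_shape, cell_polygon[:, ::-1])  # (row, col)
    nucleus_mask = polygon2mask(image_shape, nucleus_polygon[:, ::-1])
    nucleus_mask &= cell_mask
    return CellGeometry(
        cell_polygon=cell_polygon,
        nucleus_polygon=nucleus_polygon,
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        source="annotated",
    )


# ---------------------------------------------------------------------------
# rendering


def render_stack(
    scene: GroundTruthScene,
    render: RenderParams | None = None,
    seed: int | None = None,
) -> FrameStack:
    """Rasterize a scene into an 8-bit grayscale stack.

    Each frame is ``background + sum of Gaussian spots + Gaussian noise``,
    clipped and quantized to uint8. Calibration metadata is carried over from
    the scene. Noise is seeded from ``seed`` (defaults to the scene's seed).
    """
    render = render or RenderParams()
    h, w = render.image_shape
    pos = scene.positions
    if len(pos):
        if (pos["x"].min() < 0 or pos["y"].min() < 0
                or pos["x"].max() >= w or pos["y"].max() >= h):
            raise ValueError("scene positions fall outside the image bounds")
    n_frames = scene.n_frames if len(pos) else int(scene.true_params.get("n_frames", 1))
    rng = np.random.default_rng(scene.seed if seed is None else seed)
    sig = render.spot_sigma_px
    half = max(int(np.ceil(4.0 * sig)), 1)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for f in range(n_frames):
        img = np.full((h, w), float(render.background_level))
        sel = pos[pos["frame"] == f]
        for x0, y0 in sel[["x", "y"]].to_numpy():
            r0, r1 = int(np.floor(y0)) - half, int(np.floor(y0)) + half + 2
            c0, c1 = int(np.floor(x0)) - half, int(np.floor(x0)) + half + 2
            r0c, r1c = max(r0, 0), min(r1, h)
            c0c, c1c = max(c0, 0), min(c1, w)
            if r0c >= r1c or c0c >= c1c:
                continue
            yy, xx = np.mgrid[r0c:r1c, c0c:c1c]
            img[r0c:r1c, c0c:c1c] += render.peak_intensity * np.exp(
                -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sig**2)
            )
        if render.noise_sd > 0:
            img += rng.normal(0.0, render.noise_sd, size=(h, w))
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameStack(
        frames=frames,
        pixel_size_um=scene.pixel_size_um,
        frame_interval_s=scene.frame_interval_s,
    )
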