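"""End-to-end batch analyses: spatial organization and motility.

``run_spatial_pipeline`` goes stack -> detections -> alpha-shape cell
boundary (frame-0 centroids) -> region masks -> per-frame Ripley's K ->
video mean curve, plus object counts and per-region mean areas.
``run_motility_pipeline`` goes stack -> detections -> region masks ->
per-region linking, EMSD and power-law fit. Both are deterministic given
(inputs, config, seed) and write self-documenting manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .detection import FrameStack, detect_stack, summarize_counts
from .intensity import region_area_summary
from .motility import LinkParams, regional_diffusion
from .regions import (
    alpha_shape_boundary,
    assign_regions,
    build_region_masks,
    RegionMaskSet,
)
from .spatial import (
    mean_k_over_frames,
    ripley_k_per_frame,
    KFunctionCurve,
)
from .synthetic import CellGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SpatialResults",
    "MotilityResults",
    "run_spatial_pipeline",
    "run_motility_pipeline",
]


@dataclass
class PipelineConfig:
    """All pipeline parameters, with the defaults the analyses assume.

    Detection threshold 100 on the 8-bit scale and the first 50 frames;
    alpha-shape alpha 0.02; peripheral rim 60 px and perinuclear annulus
    40 px; Ripley radii 1–250 px; linker search range 9 px, memory 5 frames,
    minimum track length 20 detections; Brownian tolerance 0.1 on alpha.
    Round-trips through JSON unchanged.
    """

    pixel_size_um: float = 0.13
    frame_interval_s: float = 1.0
    threshold: int = 100
    max_frames: int | None = 50
    alpha: float = 0.02
    rim_px: int = 60
    annulus_px: int = 40
    nucleus_path: str | None = None
    radii_min_px: int = 1
    radii_max_px: int = 250
    window_area_mode: str = "cell_mask"  # or "bounding_box"
    search_range_px: float = 9.0
    memory_frames: int = 5
    min_length: int = 20
    max_lag: int = 40
    fit_lag_min: int | None = None
    fit_lag_max: int | None = None
    brownian_tol: float = 0.1
    boundary_frame: int = 0
    band_method: str = "edt"
    seed: int = 0

    @property
    def radii(self) -> np.ndarray:
        return np.arange(self.radii_min_px, self.radii_max_px + 1, dtype=float)

    @property
    def link_params(self) -> LinkParams:
        return LinkParams(self.search_range_px, self.memory_frames, self.min_length)

    @property
    def fit_lag_range(self) -> tuple[int, int] | None:
        if self.fit_lag_min is None or self.fit_lag_max is None:
            return None
        return (self.fit_lag_min, self.fit_lag_max)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SpatialResults:
    detections: pd.DataFrame
    geometry: CellGeometry
    masks: RegionMaskSet
    per_frame_counts: pd.Series
    mean_count: float
    k_curves: list[KFunctionCurve]
    mean_k: KFunctionCurve
    area_summary: pd.DataFrame
    manifest: dict


@dataclass
class MotilityResults:
    detections: pd.DataFrame
    masks: RegionMaskSet
    regional: dict  # region -> (EMSDCurve, DiffusionFit)
    manifest: dict


def _manifest(config: PipelineConfig, extra: dict) -> dict:
    from . import __version__

    return {"version": __version__, "config": asdict(config), **extra}


def _geometry_from_stack(
    stack: FrameStack,
    detections: pd.DataFrame,
    config: PipelineConfig,
    nucleus_polygon: np.ndarray | None,
) -> CellGeometry:
    """Cell boundary from alpha shape of boundary-frame centroids; nucleus from annotation."""
    from skimage.draw import polygon2mask

    pts = detections.loc[
        detections["frame"] == config.boundary_frame, ["x", "y"]
    ].to_numpy(dtype=float)
    if len(pts) < 3:
        raise ValueError(
            f"frame {config.boundary_frame} has fewer than 3 detections; "
            "cannot reconstruct the cell boundary"
        )
    shape = stack.shape
    res = alpha_shape_boundary(pts, alpha=config.alpha, image_shape=shape)
    if len(res.excluded_points):
        logger.warning(
            "alpha shape excluded %d centroid(s) from the boundary", len(res.excluded_points)
        )
    nucleus_mask = None
    if nucleus_polygon is not None:
        nucleus_mask = polygon2mask(shape, np.asarray(nucleus_polygon)[:, ::-1])
        nucleus_mask &= res.mask
    return CellGeometry(
        cell_polygon=res.polygon,
        nucleus_polygon=nucleus_polygon,
        cell_mask=res.mask,
        nucleus_mask=nucleus_mask,
        source="alpha_shape",
    )


def _region_masks(geometry: CellGeometry, config: PipelineConfig) -> RegionMaskSet:
    if geometry.nucleus_mask is not None and geometry.nucleus_mask.any():
        return build_region_masks(
            geometry.cell_mask,
            geometry.nucleus_mask,
            config.rim_px,
            config.annulus_px,
            config.pixel_size_um,
            method=config.band_method,
        )
    # without a nucleus annotation only the whole cell and its rim exist
    from .regions import peripheral_rim

    whole = np.asarray(geometry.cell_mask, bool)
    peripheral = peripheral_rim(whole, config.rim_px, config.band_method)
    return RegionMaskSet(
        whole=whole,
        peripheral=peripheral,
        perinuclear=np.zeros_like(whole),
        rim_thickness_px=config.rim_px,
        annulus_thickness_px=config.annulus_px,
        pixel_size_um=config.pixel_size_um,
    )


def run_spatial_pipeline(
    stack: FrameStack,
    config: PipelineConfig | None = None,
    nucleus_polygon: np.ndarray | None = None,
    outdir: str | Path | None = None,
) -> SpatialResults:
    """Spatial-organization analysis of one video."""
    config = config or PipelineConfig()
    if nucleus_polygon is None and config.nucleus_path:
        nucleus_polygon = lio.read_polygon(config.nucleus_path)
    detections = detect_stack(stack, config.threshold, config.max_frames)
    if len(detections) == 0:
        raise ValueError("no detections in any analyzed frame")
    geometry = _geometry_from_stack(stack, detections, config, nucleus_polygon)
    masks = _region_masks(geometry, config)
    detections = assign_regions(detections, masks)

    if config.window_area_mode == "cell_mask":
        area = float(np.count_nonzero(geometry.cell_mask))
    else:
        h, w = stack.shape
        area = float(h * w)
    curves = ripley_k_per_frame(detections, area, config.radii)
    if not curves:
        raise ValueError("fewer than 2 detections in every frame; cannot compute K")
    mean_k = mean_k_over_frames(curves)
    n_frames = min(config.max_frames or stack.n_frames, stack.n_frames)
    counts, mean_count = summarize_counts(detections, n_frames)
    areas = region_area_summary(detections, config.pixel_size_um)
    manifest = _manifest(
        config,
        {
            "analysis": "spatial",
            "n_frames_analyzed": int(n_frames),
            "window_area_px2": area,
            "mean_count": mean_count,
        },
    )
    results = SpatialResults(
        detections, geometry, masks, counts, mean_count, curves, mean_k, areas, manifest
    )
    if outdir is not None:
        _write_spatial(Path(outdir), results)
    return results


def _write_spatial(outdir: Path, r: SpatialResults) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_detections(outdir / "detections.csv", r.detections)
    r.mean_k.as_frame().to_csv(outdir / "mean_k.csv", index=False)
    r.per_frame_counts.rename("count").to_csv(outdir / "counts.csv")
    r.area_summary.to_csv(outdir / "region_areas.csv", index=False)
    lio.write_polygon(outdir / "cell_polygon.csv", r.geometry.cell_polygon)
    lio.write_mask(outdir / "cell_mask.tif", r.geometry.cell_mask)
    lio.write_json(outdir / "manifest.json", r.manifest)


def run_motility_pipeline(
    stack: FrameStack,
    config: PipelineConfig | None = None,
    nucleus_polygon: np.ndarray | None = None,
    outdir: str | Path | None = None,
) -> MotilityResults:
    """Regional diffusion analysis of one video."""
    config = config or PipelineConfig(max_frames=None)
    if nucleus_polygon is None and config.nucleus_path:
        nucleus_polygon = lio.read_polygon(config.nucleus_path)
    if stack.n_frames < config.min_length:
        raise ValueError(
            f"stack has {stack.n_frames} frames but tracks need at least "
            f"{config.min_length} detections to survive the length filter"
        )
    detections = detect_stack(stack, config.threshold, config.max_frames)
    if len(detections) == 0:
        raise ValueError("no detections in any analyzed frame")
    geometry = _geometry_from_stack(stack, detections, config, nucleus_polygon)
    masks = _region_masks(geometry, config)
    detections = assign_regions(detections, masks)
    regional = regional_diffusion(
        detections,
        config.link_params,
        max_lag=config.max_lag,
        fit_lag_range=config.fit_lag_range,
        frame_interval_s=config.frame_interval_s,
        pixel_size_um=config.pixel_size_um,
        brownian_tol=config.brownian_tol,
    )
    if not regional:
        raise ValueError(
            "no track survived the minimum-length filter "
            f"(min_length={config.min_length} detections) in any region"
        )
    manifest = _manifest(
        config,
        {
            "analysis": "motility",
            "regions_fitted": sorted(regional),
            "alphas": {k: fit.alpha for k, (_, fit) in regional.items()},
        },
    )
    results = MotilityResults(detections, masks, regional, manifest)
    if outdir is not None:
        _write_motility(Path(outdir), results)
    return results


def _write_motility(outdir: Path, r: MotilityResults) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_detections(outdir / "detections.csv", r.detections)
    for region, (curve, fit) in r.regional.items():
        curve.as_frame().to_csv(outdir / f"emsd_{region}.csv", index=False)
        lio.write_json(outdir / f"fit_{region}.json", {**fit.as_dict(), "region": region})
    lio.write_json(outdir / "manifest.json", r.manifest)
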