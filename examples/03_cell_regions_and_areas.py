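"""Reconstruct a cell boundary from puncta and compartmentalize detections.

Builds a 900 um^2 synthetic cell, scatters puncta, reconstructs the cell
outline from their positions with an alpha shape (alpha = 0.02, i.e.
Delaunay triangles with circumradius < 50 px), builds the 60 px peripheral
rim and 40 px perinuclear annulus, and reports how many detections fall in
each compartment.
"""

import numpy as np
from shapely.geometry import Polygon

import lysoquant as lq

geom = lq.make_cell_geometry(900.0, nucleus_fraction=0.15, pixel_size_um=0.13, seed=1)
h, w = geom.cell_mask.shape
scene = lq.simulate_point_pattern(
    "csr", window=Polygon(geom.cell_polygon), n_points=120, n_frames=1, seed=2
)
pts = scene.frame_points(0)

shape = lq.alpha_shape_boundary(pts, alpha=0.02, image_shape=(h, w))
print(f"true cell mask area:        {geom.cell_mask.sum()} px^2")
print(f"alpha-shape mask area:      {shape.mask.sum()} px^2 "
      f"({shape.mask.sum() / geom.cell_mask.sum():.0%} of truth)")

masks = lq.build_region_masks(geom.cell_mask, geom.nucleus_mask, 60, 40)
print(f"peripheral rim:   {masks.peripheral.sum():6d} px^2 (60 px = {60 * 0.13:.1f} um)")
print(f"perinuclear band: {masks.perinuclear.sum():6d} px^2 (40 px = {40 * 0.13:.1f} um)")

det = scene.positions.assign(area_px2=4, intensity_sum=400.0)
det = lq.assign_regions(det, masks)
print("detections per region:", det["region"].value_counts().to_dict())
print("(the alpha-shape boundary under-covers the true outline only near "
      "the margin between outermost puncta and the true edge)")
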