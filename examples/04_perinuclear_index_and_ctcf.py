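"""Perinuclear index and corrected total cell fluorescence on synthetic cells.

Renders two single-frame images over the same cell geometry: one with
puncta packed near the nucleus, one with puncta at the cell margin. The
perinuclear index PI = (I_<5 - I_>10) x 100 is strongly positive for the
clustered case and negative for the peripheral case. CTCF subtracts the
background expectation from the integrated cell signal.
"""

import numpy as np
from scipy import ndimage

import lysoquant as lq

geom = lq.make_cell_geometry(1400.0, nucleus_fraction=0.08, pixel_size_um=0.13, seed=3)
h, w = geom.cell_mask.shape
dist_um = ndimage.distance_transform_edt(~geom.nucleus_mask) * 0.13

rng = np.random.default_rng(4)
for label, band in [
    ("nucleus-hugging", geom.cell_mask & ~geom.nucleus_mask & (dist_um <= 4.0)),
    ("peripheral", geom.cell_mask & (dist_um > 12.0)),
]:
    img = np.zeros((h, w))
    pix = np.argwhere(band)
    chosen = pix[rng.choice(len(pix), size=400, replace=False)]
    img[chosen[:, 0], chosen[:, 1]] = 220.0
    profile = lq.perinuclear_index(img, geom, pixel_size_um=0.13)
    print(f"{label:>15}: PI = {profile.perinuclear_index:6.1f} "
          f"(I<5 = {profile.i_lt5_frac:.2f}, I>10 = {profile.i_gt10_frac:.2f})")

bg_roi = np.zeros((h, w), bool)
bg_roi[:20, :20] = True
img = np.full((h, w), 8.0)
img[geom.cell_mask] = 30.0
res = lq.ctcf(img, geom.cell_mask, bg_roi)
print(f"CTCF = {res.ctcf:.0f} (integrated {res.integrated_density:.0f} "
      f"- area {res.cell_area_px2} x background {res.mean_background:.1f})")
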