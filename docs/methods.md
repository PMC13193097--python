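# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `lysoquant`. Defaults are stated with units; anything
marked *implementer-chosen* has no external prescription and was fixed once
on scientific-plausibility grounds.

## Coordinate and calibration conventions

Pixel coordinates are 0-based with the origin at the top-left; `x` is the
column index and `y` the row index, continuous values allowed for particle
centers and centroids. Default calibration is 0.13 µm/px (so the 60 px
peripheral rim is 7.8 µm and the 40 px perinuclear annulus 5.2 µm) and
videos default to 50 analyzed frames.

## Detection

Frames are reduced to 8-bit grayscale: 16-bit input by full-range division
(÷257, rounded) and RGB input by the standard luminance weights
(0.299, 0.587, 0.114). Both rules are implementer-chosen conventions, made
explicit because other rescalings (min–max, percentile) would change
absolute thresholds. Foreground is *strictly greater than* the global
threshold (default 100 on the 8-bit scale; configurable to ≥). Objects are
8-connected components — pinned against an explicit flood-fill oracle in
the tests — with unweighted (binary-moment) centroids, i.e. the mean of
member pixel coordinates; intensity-weighted centroids are deliberately not
used because the upstream binarization discards the weighting anyway. No
minimum-area filter is applied by default (`min_area_px2 = 1`).

## Cell boundary and region masks

The cell outline is estimated from detected centroids (frame 0 by default;
configurable) as an alpha shape: Delaunay triangulate, keep triangles with
circumradius < 1/α, take the outer boundary of their union. α follows the
inverse-radius convention, so the default α = 0.02 keeps circumradii
< 50 px; at α → 0 the shape reduces to the convex hull. If the filtered
union is empty or disconnected the code falls back to the convex hull with
a warning, and points not belonging to any kept triangle are reported.

Bands are built with the Euclidean distance transform: the peripheral rim
is the set of cell pixels within 60 px of the exterior, the perinuclear
region the set of non-nuclear pixels within 40 px of the nucleus, clipped
to the cell mask (clipping is on by default). Euclidean bands are rotation
invariant; a compatibility mode using iterative 3×3 dilation/erosion
reproduces the Chebyshev (square-structuring-element) bands that repeated
morphological operations produce. The nucleus is an input polygon — there
is no automated nucleus segmentation — and the synthetic module supplies it
programmatically. All three region masks exclude the nuclear interior, so
a detection inside the nucleus belongs to no region. For small, round cells
the rim and annulus can overlap geometrically; detections there are
recorded with both boolean labels (`in_peripheral`, `in_perinuclear`) and
the single `region` column prefers `peripheral`, with a warning.

## Ripley's K

K(r) = A/(n(n−1)) · #{ordered pairs with d_ij ≤ r} on radii 1–250 px
(step 1), with **no edge correction**. The estimator is therefore biased
downward relative to πr² as r approaches the window scale; this bias is
intentional and documented rather than corrected, and an isotropic
correction is deliberately out of scope. The normalizing area A defaults
to the alpha-shape cell-mask pixel count (bounding box optional). Per-video
curves average all analyzed frames pointwise, skipping (and logging) frames
with fewer than two detections; group summaries use the normal
approximation mean ± 1.96·SD/√n, collapsing to the mean with a warning for
a single video.

## Tracking and diffusion

Linking is a Crocker–Grier-style optimal assignment per frame: candidate
links are track–detection pairs within the search range (9 px); among
candidates the assignment minimizing total squared displacement wins, with
birth/death priced at search_range². Candidate pairs are partitioned into
connected components so each assignment subproblem is solved exactly by the
Hungarian algorithm on a small matrix. Unmatched tracks stay "lost" but
linkable against their last known position for up to the memory (5 frames):
a particle missing for g frames reconnects iff g ≤ 5 (gap 3 joins, gap 6
splits). Track length counts detections, not spanned frames, and the
≥ 20-detection filter is inclusive.

EMSD pools every displacement pair across all retained tracks and all
overlapping start times, with equal weight per pair (a per-track-average
mode exists as an option); gap frames contribute no pairs and empty lags
are omitted. The power law EMSD(τ) = 4Dτ^α is fitted by OLS of ln EMSD on
ln τ; the natural log base cancels in the slope and is absorbed into
D = exp(intercept)/4. The default fit window is lags 1…min(20, max_lag/2)
— long lags pool few pairs and are noisy — and is always reported in the
fit object. Motion is labeled Brownian within α = 1 ± 0.1
(implementer-chosen tolerance), subdiffusive below, superdiffusive above.
Regional analysis partitions detections by region label first and runs the
whole chain independently per region; a region with no surviving tracks is
reported absent, not an error.

## Intensity metrics

The perinuclear index uses the continuous Euclidean distance from the
nuclear boundary (not successive whole-pixel dilations): I_<5 sums
intensity at distance (0, 5 µm] inside the cell, I_>10 at > 10 µm, both
normalized by whole-cell intensity (nuclear interior included by default;
configurable), and PI = (I_<5 − I_>10) × 100 ∈ [−100, 100]. The 5–10 µm
zone is computed and reported but does not enter the index. CTCF is
integrated cell intensity minus cell area × mean of a user-supplied
background ROI; negative values pass through.

## Synthetic scenes

The generator emulates the imaging conditions the analysis assumes: HeLa-
scale cells of 500–1400 µm² (default 900 µm²) at 0.13 µm/px, 50-frame
videos of punctate signals.

- **Point patterns**: CSR as uniform points (fixed-n by default — removing
  count variance from estimator tests — or Poisson counts), clustered as a
  Thomas-type parent–offspring process (uniform parents, Gaussian
  offspring, resampled into the window), dispersed by sequential hard-core
  rejection that errors when packing is infeasible. Frames are independent
  draws.
- **Trajectories**: Brownian motion with per-axis increments
  N(0, 2DΔt); confined motion adds radial reflection at a circular corral
  centred on each start; directed motion adds constant drift (random fixed
  headings for scalar speed). Window boundaries reflect rather than wrap,
  because wrapping would hand the linker spurious large displacements.
- **Geometry**: disk or Fourier-perturbed "blob" cell polygons rescaled to
  the requested area (pixel-mask area within 2%), with a concentric nucleus
  of a given area fraction.
- **Rendering**: frame = background (20) + Gaussian spots (σ = 1.5 px,
  peak 180) + additive Gaussian noise (SD 5), quantized to 8-bit. These
  render defaults are implementer-chosen — the real videos' noise and spot
  intensity statistics are not prescribed anywhere — and are validated only
  in the sense that default spots are recoverable by the default threshold.
  There is no PSF/optics model, no photobleaching, no shot noise, no 3D;
  passing tests demonstrate estimator correctness on recoverable synthetic
  data, not robustness to real microscope noise.

All randomness flows from one seeded `numpy` generator per call; identical
arguments and seed give bit-identical scenes, and the pipelines are fully
deterministic given (input, config, seed).

## Validation problem sizes

The validation suite recovers α = 1.0 ± 0.05 and prefactor 4 ± 10% from
500 Brownian tracks (D = 0.25 px²/frame, 100 frames) passed through the
full linking chain; the simulation window (3000×3000 px) is sized so that
encounters within the 9 px search range are rare and linking is essentially
exact. Regime sidedness is checked over 20 replicates per regime (100
tracks each), requiring each replicate's α to sit on the correct side of 1
by more than twice the fitted slope's standard error. The acceptance script
uses 300-track confined (corral radius 5 px, D = 0.5, 300 frames) and
directed (speed 0.5 px/frame, D = 0.05, 200 frames) simulations, fitted
over lags 1–50 and 1–20 respectively.

## Known limitations

- Threshold segmentation cannot split touching puncta (no watershed); in
  dense CSR scenes this removes exactly the closest point pairs, deflating
  K at radii below a few spot diameters and slightly undercounting objects.
- The alpha-shape boundary under-covers the true cell outline by the margin
  between the outermost detected puncta and the membrane.
- The uncorrected K estimator should only be compared between samples
  analyzed with the same window convention, not to πr² at large r.
- Linking assumes mostly-separated particles; identity swaps are possible
  when spacing approaches the search range.
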