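# lysoquant

Quantitative analysis of lysosome organization and motility from
time-lapse fluorescence microscopy.

Live-cell imaging of dextran- or LAMP1-labeled lysosomes produces videos of
punctate signals whose number, size, subcellular distribution and movement
report on membrane-traffic phenotypes (for example, redistribution of
lysosomes between the perinuclear cloud and the cell periphery after a
knockdown). `lysoquant` implements that measurement pipeline as a tested,
reusable Python library, together with a ground-truthed synthetic-scene
generator, so every stage can be validated without microscope data.

## What it computes

- **Detection** — frames are converted to 8-bit grayscale, binarized at a
  global intensity threshold (default 100), and puncta are extracted as
  8-connected components with binary-moment centroids, areas and summed
  intensities.
- **Cell regions** — the cell outline is reconstructed from the detected
  centroids by an alpha shape (keep Delaunay triangles with circumradius
  < 1/α; default α = 0.02, i.e. < 50 px). The peripheral cytoplasm is the
  inward 60 px rim (7.8 µm at 0.13 µm/px) and the perinuclear region the
  outward 40 px annulus (5.2 µm) around an annotated nucleus.
- **Spatial statistics** — the uncorrected Ripley's K function

  K(r) = A / (n(n−1)) · #{ordered pairs with d ≤ r},

  compared to the complete-spatial-randomness baseline πr² on radii
  1–250 px, averaged over the first 50 frames per video and across videos
  with 95% confidence intervals.
- **Motility** — Crocker–Grier-style trajectory linking (search range 9 px,
  gap memory 5 frames), a ≥ 20-detection length filter, the pooled ensemble
  mean-squared displacement EMSD(τ) = ⟨Δx² + Δy²⟩ and a log–log OLS fit of

  EMSD(τ) = 4 D τ^α,

  classifying motion as subdiffusive (α < 1), Brownian (α ≈ 1) or
  superdiffusive (α > 1), per region.
- **Intensity metrics** — the perinuclear index PI = (I_<5 − I_>10) × 100
  from 5/10 µm distance bands around the nucleus, and corrected total cell
  fluorescence CTCF = integrated density − cell area × mean background.

## Worked example

`examples/02_tracking_and_diffusion.py` simulates three motion regimes,
pushes the anonymous per-frame detections through the full tracking chain
and fits the power law:

```
 brownian: alpha = 1.006  D_app = 0.2481 px^2/frame^alpha  regime = brownian       (normal diffusion, alpha ~ 1)
 confined: alpha = 0.750  D_app = 0.5131 px^2/frame^alpha  regime = subdiffusive   (corralled, subdiffusive)
 directed: alpha = 1.848  D_app = 0.0977 px^2/frame^alpha  regime = superdiffusive (drift, superdiffusive)
```

The Brownian scene was simulated with D = 0.25 px²/frame, and the fitted
exponent and prefactor recover it: α ≈ 1 and D_app ≈ 0.25. The confined
corrals flatten the EMSD (α < 1); constant drift bends it up (α → 2).
The other example scripts cover point patterns and Ripley's K, alpha-shape
region construction, the perinuclear index/CTCF, and the two end-to-end
pipelines on a rendered video.

A thin CLI mirrors the library (`lysoquant simulate | detect | regions |
ripley | track | msd | perinuclear | ctcf | run-spatial | run-motility`);
each subcommand reads and writes the CSV/JSON/TIFF interchange formats, so
stages can be chained or run standalone.

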