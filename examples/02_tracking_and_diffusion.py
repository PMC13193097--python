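"""Recover motion regimes from simulated trajectories.

Simulates Brownian, confined and directed motion, runs the full chain
(link with 9 px search range and 5-frame memory, keep tracks >= 20
detections, pooled ensemble MSD, log-log power-law fit) and prints the
fitted diffusion exponent alpha: ~1 for Brownian, < 1 confined, > 1 directed.
"""

import lysoquant as lq
from lysoquant.motility import LinkParams

for regime, kwargs, note in [
    ("brownian", dict(d=0.25), "normal diffusion, alpha ~ 1"),
    ("confined", dict(d=0.5, corral_radius_px=5.0), "corralled, subdiffusive"),
    ("directed", dict(d=0.05, velocity=0.5), "drift, superdiffusive"),
]:
    scene = lq.simulate_trajectories(
        regime, n_particles=200, n_frames=100, window=(2000, 2000), seed=8, **kwargs
    )
    # feed anonymous detections through the linker, as real videos would be
    detections = scene.positions[["frame", "x", "y"]]
    tracks = lq.filter_tracks(lq.link_trajectories(detections, LinkParams()), 20)
    curve = lq.emsd(tracks, 20)
    fit = lq.fit_power_law(curve, (1, 20))
    print(
        f"{regime:>9}: alpha = {fit.alpha:5.3f}  D_app = {fit.d_apparent:6.4f} "
        f"px^2/frame^alpha  regime = {fit.regime:<14} ({note})"
    )
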