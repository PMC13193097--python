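"""Linking, track filtering, ensemble MSD and power-law fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lysoquant as lq
from lysoquant.motility import LinkParams


def det_table(rows):
    """rows of (frame, x, y) -> detection table."""
    return pd.DataFrame(rows, columns=["frame", "x", "y"])


def emsd_bruteforce(tracks, max_lag):
    """Triple loop: track x start frame x lag, pooling all pairs."""
    sums = {t: 0.0 for t in range(1, max_lag + 1)}
    counts = {t: 0 for t in range(1, max_lag + 1)}
    for _, grp in tracks.groupby("particle"):
        by_frame = {int(r.frame): (r.x, r.y) for r in grp.itertuples()}
        for f in by_frame:
            for tau in range(1, max_lag + 1):
                if f + tau in by_frame:
                    x0, y0 = by_frame[f]
                    x1, y1 = by_frame[f + tau]
                    sums[tau] += (x1 - x0) ** 2 + (y1 - y0) ** 2
                    counts[tau] += 1
    lags = [t for t in sums if counts[t] > 0]
    return {t: sums[t] / counts[t] for t in lags}


def optimal_assignment_bruteforce(prev, cur, sr):
    """Exhaustive minimum-cost matching with births/deaths at sr^2."""
    m, n = len(prev), len(cur)
    best, best_cost = None, np.inf
    for k in range(min(m, n) + 1):
        for ti in itertools.combinations(range(m), k):
            for dj in itertools.permutations(range(n), k):
                cost = 0.0
                ok = True
                for i, j in zip(ti, dj):
                    d2 = (prev[i][0] - cur[j][0]) ** 2 + (prev[i][1] - cur[j][1]) ** 2
                    if d2 > sr**2:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += (m - k) * sr**2 + (n - k) * sr**2
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best = dict(zip(dj, ti))
    return best


class TestLinking:
    def test_two_separated_particles_two_tracks(self):
        rng = np.random.default_rng(0)
        rows = []
        p0, p1 = np.array([10.0, 10.0]), np.array([60.0, 60.0])
        for f in range(50):
            rows.append((f, *p0))
            rows.append((f, *p1))
            p0 = p0 + rng.uniform(-1, 1, 2)
            p1 = p1 + rng.uniform(-1, 1, 2)
        tracks = lq.link_trajectories(det_table(rows))
        assert tracks["particle"].nunique() == 2
        sizes = tracks.groupby("particle").size()
        assert (sizes == 50).all()

    @pytest.mark.parametrize("gap,expected_tracks", [(3, 1), (6, 2)])
    def test_memory_boundary(self, gap, expected_tracks):
        # particle vanishes for `gap` frames; memory 5 joins gaps <= 5
        rows = [(f, 50.0 + 0.1 * f, 50.0) for f in range(10)]
        rows += [(f, 50.0 + 0.1 * f, 50.0) for f in range(10 + gap, 25 + gap)]
        tracks = lq.link_trajectories(det_table(rows), LinkParams(9.0, 5, 2))
        assert tracks["particle"].nunique() == expected_tracks

    def test_exact_recovery_of_separable_brownian_scene(self):
        # starts on a coarse grid: spacing always > 2 x search range
        starts = np.array([[40.0 * i + 20, 40.0 * j + 20] for i in range(6) for j in range(5)])
        scene = lq.simulate_trajectories(
            "brownian", n_particles=30, n_frames=40, window=(260, 220),
            d=0.2, seed=3, start_positions=starts,
        )
        det = scene.positions[["frame", "x", "y"]]
        tracks = lq.link_trajectories(det)
        assert tracks["particle"].nunique() == 30
        # recovered tracks coincide with ground truth point-for-point
        truth = scene.positions.sort_values(["particle", "frame"])
        merged = tracks.merge(truth, on=["frame", "x", "y"])
        groups = merged.groupby("particle_x")["particle_y"].nunique()
        assert (groups == 1).all()
        assert len(merged) == len(truth)

    def test_assignment_matches_exhaustive_oracle(self):
        # many random 2-frame instances: frame-to-frame links must equal the
        # exhaustive minimum-cost matching
        rng = np.random.default_rng(42)
        for _ in range(30):
            m, n = rng.integers(1, 5), rng.integers(1, 5)
            prev = rng.uniform(0, 30, size=(m, 2))
            cur = rng.uniform(0, 30, size=(n, 2))
            rows = [(0, x, y) for x, y in prev] + [(1, x, y) for x, y in cur]
            tracks = lq.link_trajectories(det_table(rows), LinkParams(9.0, 0, 2))
            got = {}
            for _, grp in tracks.groupby("particle"):
                f0 = grp[grp["frame"] == 0]
                f1 = grp[grp["frame"] == 1]
                if len(f0) and len(f1):
                    i = int(np.argmin(np.hypot(prev[:, 0] - f0["x"].iloc[0], prev[:, 1] - f0["y"].iloc[0])))
                    j = int(np.argmin(np.hypot(cur[:, 0] - f1["x"].iloc[0], cur[:, 1] - f1["y"].iloc[0])))
                    got[j] = i
            want = optimal_assignment_bruteforce(prev, cur, 9.0)
            # same total cost (ties may swap identities)
            def cost(match):
                c = 0.0
                for j, i in match.items():
                    c += (prev[i][0] - cur[j][0]) ** 2 + (prev[i][1] - cur[j][1]) ** 2
                c += (len(prev) - len(match)) * 81.0 + (len(cur) - len(match)) * 81.0
                return c

            assert cost(got) == pytest.approx(cost(want))

    def test_empty_input(self):
        out = lq.link_trajectories(pd.DataFrame(columns=["frame", "x", "y"]))
        assert len(out) == 0


class TestFilter:
    def test_inclusive_length_boundary(self):
        rows = []
        for pid, length in enumerate([10, 19, 20, 25]):
            for f in range(length):
                rows.append((pid, f, float(pid), 0.0))
        tracks = pd.DataFrame(rows, columns=["particle", "frame", "x", "y"])
        kept = lq.filter_tracks(tracks, 20)
        assert kept["particle"].nunique() == 2
        assert set(kept["particle"]) == {2, 3}

    def test_min_length_two_keeps_everything(self):
        tracks = pd.DataFrame({"particle": [0, 0], "frame": [0, 1], "x": [0.0, 1.0], "y": [0.0, 0.0]})
        assert len(lq.filter_tracks(tracks, 2)) == 2

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["particle", "frame", "x", "y"])
        assert len(lq.filter_tracks(empty, 20)) == 0


class TestEMSD:
    def test_stationary_track_zero(self):
        tracks = pd.DataFrame({"particle": 0, "frame": range(10), "x": 5.0, "y": 5.0})
        curve = lq.emsd(tracks, 5)
        assert np.allclose(curve.emsd_px2, 0.0)

    def test_ballistic_track_tau_squared(self):
        tracks = pd.DataFrame({"particle": 0, "frame": range(30), "x": np.arange(30.0), "y": 0.0})
        curve = lq.emsd(tracks, 10)
        assert np.allclose(curve.emsd_px2, curve.lags.astype(float) ** 2)

    def test_matches_bruteforce_triple_loop_with_gaps(self, rng):
        rows = []
        for pid in range(6):
            frames = sorted(rng.choice(40, size=25, replace=False))
            x, y = rng.uniform(0, 100, 2)
            for f in frames:
                x += rng.normal()
                y += rng.normal()
                rows.append((pid, f, x, y))
        tracks = pd.DataFrame(rows, columns=["particle", "frame", "x", "y"])
        curve = lq.emsd(tracks, 15)
        want = emsd_bruteforce(tracks, 15)
        assert curve.lags.tolist() == sorted(want)
        for lag, val in zip(curve.lags, curve.emsd_px2):
            assert val == pytest.approx(want[lag])

    def test_brownian_matches_4dtau(self):
        d = 0.25
        scene = lq.simulate_trajectories(
            "brownian", n_particles=500, n_frames=60, window=(4000, 4000), d=d, seed=6
        )
        curve = lq.emsd(scene.positions, 20)
        for tau, val, npairs in zip(curve.lags, curve.emsd_px2, curve.n_pairs):
            expect = 4 * d * tau
            # 3 SE of a chi-square mean with ~npairs/tau independent pairs
            se = expect * np.sqrt(2.0 / (npairs / tau))
            assert abs(val - expect) < 3 * se

    def test_translation_invariance(self, rng):
        tracks = pd.DataFrame({
            "particle": np.repeat([0, 1], 20),
            "frame": np.tile(range(20), 2),
            "x": rng.normal(size=40).cumsum(),
            "y": rng.normal(size=40).cumsum(),
        })
        a = lq.emsd(tracks, 8)
        shifted = tracks.assign(x=tracks["x"] + 123.0, y=tracks["y"] - 77.0)
        b = lq.emsd(shifted, 8)
        assert np.allclose(a.emsd_px2, b.emsd_px2, rtol=1e-10)


class TestPowerLawFit:
    def test_exact_linear_curve(self):
        lags = np.arange(1, 11)
        curve = lq.EMSDCurve(lags, 2.0 * lags, np.ones(10, int))
        fit = lq.fit_power_law(curve, (1, 10))
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.d_apparent == pytest.approx(0.5, abs=1e-12)
        assert fit.regime == "brownian"

    def test_exact_superdiffusive_curve(self):
        lags = np.arange(1, 11)
        curve = lq.EMSDCurve(lags, 2.0 * lags**1.5, np.ones(10, int))
        fit = lq.fit_power_law(curve, (1, 10))
        assert fit.alpha == pytest.approx(1.5, abs=1e-12)
        assert fit.d_apparent == pytest.approx(0.5, abs=1e-12)
        assert fit.regime == "superdiffusive"
        assert fit.r_squared == pytest.approx(1.0)

    def test_simulated_brownian_alpha_and_prefactor(self):
        d = 0.25
        scene = lq.simulate_trajectories(
            "brownian", n_particles=400, n_frames=80, window=(4000, 4000), d=d, seed=19
        )
        fit = lq.fit_power_law(lq.emsd(scene.positions, 20), (1, 20))
        assert fit.alpha == pytest.approx(1.0, abs=0.05)
        assert np.exp(fit.intercept_log) / d == pytest.approx(4.0, rel=0.10)

    def test_nonpositive_values_rejected_with_lags_listed(self):
        lags = np.arange(1, 6)
        curve = lq.EMSDCurve(lags, np.array([1.0, 0.0, 2.0, 3.0, 4.0]), np.ones(5, int))
        with pytest.raises(ValueError, match=r"\[2\]"):
            lq.fit_power_law(curve, (1, 5))

    def test_regime_ordering_confined_brownian_directed(self):
        alphas = {}
        for regime, kw in [
            ("confined", dict(d=0.5, corral_radius_px=4.0)),
            ("brownian", dict(d=0.25)),
            ("directed", dict(d=0.05, velocity=0.5)),
        ]:
            scene = lq.simulate_trajectories(
                regime, n_particles=150, n_frames=100, window=(2000, 2000), seed=23, **kw
            )
            alphas[regime] = lq.fit_power_law(lq.emsd(scene.positions, 20), (1, 20)).alpha
        assert alphas["confined"] < alphas["brownian"] < alphas["directed"]


class TestRegionalDiffusion:
    def test_regions_fitted_independently(self):
        g = lq.make_cell_geometry(1400.0, 0.08, 0.13, "disk", seed=2)
        masks = lq.build_region_masks(g.cell_mask, g.nucleus_mask, 60, 40)
        h, w = masks.whole.shape
        # Brownian particles across the whole cell
        scene = lq.simulate_trajectories(
            "brownian", n_particles=150, n_frames=60, window=(0, 0, w - 1, h - 1),
            d=0.2, seed=3,
        )
        det = scene.positions.rename(columns={"particle": "truth"})
        det["area_px2"] = 1
        det["intensity_sum"] = 200.0
        det = lq.assign_regions(det, masks)
        out = lq.regional_diffusion(det, LinkParams(9.0, 5, 20), max_lag=20)
        assert "whole" in out
        for region, (curve, fit) in out.items():
            assert abs(fit.alpha - 1.0) < 0.35

    def test_region_without_tracks_absent(self):
        from scipy import ndimage

        g = lq.make_cell_geometry(1400.0, 0.08, 0.13, "disk", seed=2)
        masks = lq.build_region_masks(g.cell_mask, g.nucleus_mask, 60, 40)
        # particles drifting slowly inside the rim (away from its edges);
        # none ever enters the perinuclear annulus
        edt = ndimage.distance_transform_edt(g.cell_mask)
        pix = np.argwhere(masks.peripheral & (edt > 10) & (edt < 50))[::400][:20]
        rows = []
        for f in range(30):
            for pid, (r, c) in enumerate(pix):
                rows.append((f, float(c) + 0.05 * f, float(r)))
        det = pd.DataFrame(rows, columns=["frame", "x", "y"])
        det["area_px2"] = 1
        det["intensity_sum"] = 200.0
        det = lq.assign_regions(det, masks)
        out = lq.regional_diffusion(det, LinkParams(9.0, 5, 20), max_lag=10)
        assert "perinuclear" not in out
        assert "whole" in out and "peripheral" in out
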