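"""Point-process simulators and the synthetic AFM renderer."""

import warnings

import numpy as np
import pytest

from colloid2d import (ClusterParams, MCParams, PointPattern, RenderConfig,
                       Repulsion, SimConfig, ValidationError,
                       last_acceptance_rate, quadrat_counts, render_afm_image,
                       simulate, simulate_cluster, simulate_csr,
                       simulate_hardcore, simulate_soft_repulsive)


class TestCsr:
    def test_empty(self):
        assert simulate_csr(SimConfig(n_points=0)).n == 0

    def test_seed_determinism(self):
        a = simulate_csr(SimConfig(n_points=500, seed=9))
        b = simulate_csr(SimConfig(n_points=500, seed=9))
        np.testing.assert_array_equal(a.points, b.points)

    def test_dispersion_index_near_unity(self):
        inside = 0
        for seed in range(10):
            p = simulate_csr(SimConfig(n_points=10_000, seed=seed))
            res = quadrat_counts(p)
            df = res.counts.size - 1
            from scipy.stats import chi2
            lo, hi = chi2.ppf(0.025, df) / df, chi2.ppf(0.975, df) / df
            inside += lo < res.dispersion_index < hi
        assert inside >= 8


class TestHardcore:
    def test_min_distance_enforced_exactly(self):
        p = simulate_hardcore(SimConfig(n_points=300, process="hardcore",
                                        hardcore_radius=200.0, seed=2))
        assert p.n == 300
        w, h = p.window
        dx = np.abs(p.points[:, None, 0] - p.points[None, :, 0])
        dy = np.abs(p.points[:, None, 1] - p.points[None, :, 1])
        dx = np.minimum(dx, w - dx)
        dy = np.minimum(dy, h - dy)
        d = np.hypot(dx, dy)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 200.0

    def test_giant_core_leaves_one_point(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = simulate_hardcore(SimConfig(window=(1000.0, 1000.0),
                                            n_points=50, process="hardcore",
                                            hardcore_radius=5000.0, seed=1))
        assert p.n == 1

    def test_infeasible_packing_warns(self):
        with pytest.warns(UserWarning, match="infeasible"):
            simulate_hardcore(SimConfig(window=(1000.0, 1000.0), n_points=500,
                                        process="hardcore",
                                        hardcore_radius=100.0, seed=0))

    def test_seed_determinism(self):
        a = simulate_hardcore(SimConfig(n_points=200, process="hardcore",
                                        hardcore_radius=100.0, seed=5))
        b = simulate_hardcore(SimConfig(n_points=200, process="hardcore",
                                        hardcore_radius=100.0, seed=5))
        np.testing.assert_array_equal(a.points, b.points)


class TestSoftRepulsive:
    def test_ideal_gas_limit_stays_csr(self):
        cfg = SimConfig(n_points=600, process="soft_repulsive",
                        repulsion=Repulsion(epsilon=0.0, coulomb=0.0),
                        mc=MCParams(n_sweeps=20, max_step=500.0), seed=3)
        p = simulate_soft_repulsive(cfg)
        res = quadrat_counts(p)
        from scipy.stats import chi2
        df = res.counts.size - 1
        assert chi2.ppf(0.005, df) / df < res.dispersion_index \
            < chi2.ppf(0.995, df) / df

    def test_strong_repulsion_builds_short_range_order(self):
        from colloid2d import RDFConfig, compute_rdf, fig1_like
        cfg = fig1_like(seed=3)
        p = simulate_soft_repulsive(cfg)
        res = compute_rdf(p, RDFConfig(r_max=2500.0, bin_width=50.0,
                                       edge_correction="periodic"))
        low = res.g[res.r < cfg.repulsion.lj_sigma]
        assert np.all(low < 0.2)          # exclusion zone
        assert res.g.max() > 1.0          # first-shell peak
        assert 0.1 < last_acceptance_rate() < 0.9

    def test_seed_determinism(self):
        cfg = SimConfig(n_points=50, process="soft_repulsive",
                        mc=MCParams(n_sweeps=10), seed=8)
        np.testing.assert_array_equal(simulate_soft_repulsive(cfg).points,
                                      simulate_soft_repulsive(cfg).points)


class TestCluster:
    def test_zero_scatter_collapses_onto_parents(self):
        cfg = SimConfig(process="cluster", seed=6,
                        cluster=ClusterParams(n_parents=7,
                                              offspring_per_parent_mean=30.0,
                                              offspring_sd=0.0))
        p = simulate_cluster(cfg)
        assert np.unique(np.round(p.points, 9), axis=0).shape[0] == 7

    def test_expected_total_count(self):
        totals = [simulate_cluster(SimConfig(
            process="cluster", seed=s,
            cluster=ClusterParams(n_parents=20,
                                  offspring_per_parent_mean=50.0))).n
            for s in range(20)]
        assert np.mean(totals) == pytest.approx(1000, rel=0.1)

    def test_super_poisson_signature(self):
        hits = 0
        for seed in range(10):
            p = simulate_cluster(SimConfig(
                process="cluster", seed=seed,
                cluster=ClusterParams(n_parents=20,
                                      offspring_per_parent_mean=50.0,
                                      offspring_sd=200.0)))
            res = quadrat_counts(p)
            hits += res.dispersion_index > 1.0
        assert hits >= 9


class TestRender:
    def test_empty_pattern_zero_noise(self):
        p = PointPattern(points=np.empty((0, 2)), window=(1000.0, 1000.0))
        hm = render_afm_image(p, RenderConfig(pixel_size=10.0, noise_sd=0.0))
        assert np.all(hm.heights == 0.0)

    def test_peak_at_particle(self):
        p = PointPattern(points=[[500.0, 300.0]], window=(1000.0, 600.0))
        hm = render_afm_image(p, RenderConfig(pixel_size=10.0,
                                              bump_height=15.0,
                                              bump_sigma=25.0, noise_sd=0.0))
        i, j = np.unravel_index(hm.heights.argmax(), hm.shape)
        assert (j * 10.0, i * 10.0) == (500.0, 300.0)
        assert hm.heights.max() == pytest.approx(15.0, rel=1e-6)

    def test_per_particle_heights_used(self):
        p = PointPattern(points=[[200.0, 200.0], [800.0, 800.0]],
                         window=(1000.0, 1000.0),
                         heights=[1.0, 15.0])
        hm = render_afm_image(p, RenderConfig(pixel_size=10.0, noise_sd=0.0))
        assert hm.heights.max() == pytest.approx(15.0, rel=1e-3)

    def test_full_round_trip_recovers_positions(self, rng):
        from colloid2d import DetectionConfig, detect_particles
        pts = rng.uniform(1000, 9000, size=(40, 2))
        # enforce generous separation by thinning close pairs
        keep = np.ones(len(pts), dtype=bool)
        for i in range(len(pts)):
            for j in range(i):
                if keep[j] and np.hypot(*(pts[i] - pts[j])) < 300:
                    keep[i] = False
        pts = pts[keep]
        pattern = PointPattern(points=pts, window=(10_000.0, 10_000.0))
        hm = render_afm_image(pattern, RenderConfig(pixel_size=20.0,
                                                    bump_height=2.0,
                                                    bump_sigma=30.0,
                                                    noise_sd=0.1, seed=1))
        parts = detect_particles(hm, DetectionConfig(height_threshold=0.5))
        assert len(parts) == len(pts)
        det = np.array(sorted([(q.x, q.y) for q in parts]))
        ref = np.array(sorted(map(tuple, pts)))
        assert np.abs(det - ref).max() < 20.0  # within one pixel


def test_dispatch_and_unknown_process():
    assert simulate(SimConfig(n_points=5, process="csr", seed=0)).n == 5
    with pytest.raises(ValidationError):
        simulate(SimConfig(n_points=5, process="banana"))
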