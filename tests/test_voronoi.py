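"""Tessellation geometry, cluster search, and classification invariants."""

import numpy as np
import pytest

from qspt.simulate import ClusterSimConfig, simulate_clustered_localizations
from qspt.types import Cluster, LocalizationMap
from qspt.voronoi import (VoronoiClusterFinder, build_tessellation,
                          classify_detections, find_clusters,
                          voronoi_area_histogram)


def poisson_map(n, L, seed):
    pts = np.random.default_rng(seed).uniform(0, L, size=(n, 2))
    return LocalizationMap(points=pts, fov_bounds=(0, 0, L, L))


class TestBuildTessellation:
    def test_lattice_interior_cells_equal_area(self):
        s = 10.0
        xx, yy = np.meshgrid(np.arange(8), np.arange(8))
        pts = np.column_stack([xx.ravel(), yy.ravel()]) * s + s / 2
        m = LocalizationMap(points=pts, fov_bounds=(0, 0, 8 * s, 8 * s))
        tess = build_tessellation(m)
        np.testing.assert_allclose(tess.areas, s**2, rtol=1e-9)

    def test_four_corner_symmetry(self):
        pts = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [1.5, 1.5]])
        tess = build_tessellation(LocalizationMap(points=pts, fov_bounds=(0, 0, 2, 2)))
        np.testing.assert_allclose(tess.areas, 1.0, rtol=1e-12)

    def test_partition_conservation(self):
        m = poisson_map(400, 1000.0, seed=2)
        tess = build_tessellation(m)
        assert abs(tess.areas.sum() - 1e6) / 1e6 < 1e-6

    def test_neighbor_relation_symmetric(self):
        tess = build_tessellation(poisson_map(200, 500.0, seed=3))
        for i, nbrs in enumerate(tess.neighbors):
            for j in nbrs:
                assert i in tess.neighbors[j]

    def test_duplicates_collapsed_with_multiplicity(self):
        pts = np.vstack([poisson_map(50, 100.0, seed=4).points,
                         [[10.0, 10.0]] * 3])
        m = LocalizationMap(points=pts, fov_bounds=(0, 0, 100, 100))
        tess = build_tessellation(m)
        assert tess.multiplicity.sum() == 53
        assert tess.multiplicity.max() >= 3

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            build_tessellation(LocalizationMap(points=np.zeros((3, 2)) + [[0, 0]],
                                               fov_bounds=(0, 0, 1, 1)))

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            build_tessellation(LocalizationMap(points=pts, fov_bounds=(0, 0, 5, 5)))


class TestFindClusters:
    def test_dense_disks_recovered(self):
        cfg = ClusterSimConfig(seed=1)
        lm, labels = simulate_clustered_localizations(cfg)
        tess = build_tessellation(lm)
        clusters = find_clusters(tess)
        assert len(clusters) >= cfg.n_clusters

    def test_nine_cell_component_is_not_a_cluster(self):
        cfg = ClusterSimConfig(n_clusters=1, locs_per_cluster=9,
                               background_density=30.0, fov=2000.0, seed=6)
        lm, labels = simulate_clustered_localizations(cfg)
        tess = build_tessellation(lm)
        clusters = find_clusters(tess, min_cells=10)
        # every reported cluster satisfies the >= 10 connected cells rule,
        # so the 9-member disk can only appear fused with retained background
        assert all(len(c.member_cells) >= 10 for c in clusters)

    def test_threshold_monotonicity(self):
        cfg = ClusterSimConfig(seed=2)
        lm, _ = simulate_clustered_localizations(cfg)
        tess = build_tessellation(lm)
        counts = []
        for pct in (50.0, 40.0, 30.0):
            cls = find_clusters(tess, area_percentile=pct)
            counts.append(sum(c.n_locs for c in cls))
        assert counts[0] >= counts[1] >= counts[2]

    def test_cluster_metric_invariants(self):
        cfg = ClusterSimConfig(seed=3)
        lm, _ = simulate_clustered_localizations(cfg)
        tess = build_tessellation(lm)
        for c in find_clusters(tess):
            assert c.radius == pytest.approx(np.sqrt(c.area / np.pi))
            assert c.density == pytest.approx(100.0 * c.n_locs / c.area)
            assert c.n_locs >= 10


class TestScaleEquivariance:
    def test_rescaling_scales_radii_and_preserves_fractions(self):
        cfg = ClusterSimConfig(seed=5)
        lm, _ = simulate_clustered_localizations(cfg)
        f1 = VoronoiClusterFinder(fov_bounds=lm.fov_bounds).fit(lm.points)
        c = 3.0
        b = tuple(np.asarray(lm.fov_bounds) * c)
        f2 = VoronoiClusterFinder(size_cut=50.0 * c, fov_bounds=b).fit(lm.points * c)
        r1 = sorted(cl.radius for cl in f1.clusters_)
        r2 = sorted(cl.radius for cl in f2.clusters_)
        np.testing.assert_allclose(np.array(r2), c * np.array(r1), rtol=1e-8)
        for k in f1.fractions_:
            assert f1.fractions_[k] == pytest.approx(f2.fractions_[k])


class TestClassifyDetections:
    def test_zero_clusters_all_unclustered(self):
        tess = build_tessellation(poisson_map(100, 500.0, seed=7))
        fr = classify_detections([], tess)
        assert fr == {"frac_unclustered": 1.0, "frac_small": 0.0, "frac_large": 0.0}

    def test_radius_tie_at_cut_goes_large(self):
        tess = build_tessellation(poisson_map(100, 500.0, seed=8))
        n = tess.multiplicity.sum()
        cl = Cluster(member_cells=np.arange(10), n_locs=int(n), area=np.pi * 50.0**2,
                     radius=50.0, density=1.0)
        fr = classify_detections([cl], tess, size_cut=50.0)
        assert fr["frac_large"] == 1.0 and fr["frac_small"] == 0.0

    def test_fractions_sum_to_one(self):
        cfg = ClusterSimConfig(seed=9)
        lm, _ = simulate_clustered_localizations(cfg)
        f = VoronoiClusterFinder(fov_bounds=lm.fov_bounds).fit(lm.points)
        assert sum(f.fractions_.values()) == pytest.approx(1.0)


class TestAreaHistogram:
    def test_mean_bounded_area_matches_inverse_density(self):
        # a tessellation partitions the window: mean cell area ≈ 1/ρ
        L, n = 2000.0, 3000
        tess = build_tessellation(poisson_map(n, L, seed=10))
        rho = n / L**2
        assert np.mean(tess.areas) == pytest.approx(1 / rho, rel=0.05)

    def test_doubling_density_halves_mean_area(self):
        t1 = build_tessellation(poisson_map(1000, 1000.0, seed=11))
        t2 = build_tessellation(poisson_map(2000, 1000.0, seed=11))
        assert np.mean(t2.areas) == pytest.approx(np.mean(t1.areas) / 2, rel=0.05)

    def test_identical_maps_ks_zero(self):
        t = build_tessellation(poisson_map(500, 800.0, seed=12))
        rep = voronoi_area_histogram([t], other=[t])
        assert rep["ks_stat"] == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            voronoi_area_histogram([])
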