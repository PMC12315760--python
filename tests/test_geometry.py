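"""Geometry generators, characterization and erosion."""

import math

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vascmrf import GridSpec
from vascmrf.geometry import (NetworkParams, VoxelGeometry, bvf_tolerance,
                              characterize_voxel, erode_voxel, fixed_radius,
                              grow_network_voxel, make_cylinder_voxel,
                              make_disk_voxel, measure_bvf,
                              min_feret_diameter,
                              sample_isotropic_directions)
from vascmrf.geometry import _cylinder_mask


GRID_2D = GridSpec((124, 124, 1), (2.0, 2.0, 2.0))  # 248 x 248 µm plane


class TestDisks:
    def test_zero_target_gives_empty_mask(self):
        v = make_disk_voxel(GRID_2D, radius=5.0, target_bvf=0.0, seed=0)
        assert v.bvf == 0.0
        assert not v.occupancy.any()
        assert v.provenance == "disk2d"

    def test_single_disk_matches_analytic_area(self):
        # one 10 µm disk in a 248x248 µm plane: bvf = 100*pi*10^2/248^2
        analytic = 100.0 * math.pi * 10.0**2 / 248.0**2
        v = make_disk_voxel(GRID_2D, radius=10.0, target_bvf=analytic, seed=3)
        assert v.meta["n_disks"] == 1
        assert v.bvf == pytest.approx(analytic, rel=0.05)  # rasterization

    def test_disk_count_near_nonoverlapping_estimate(self):
        # 3% of the plane with 5 µm disks: ~23 disks if non-overlapping;
        # overlaps can only waste area, so the count is >= that
        v = make_disk_voxel(GRID_2D, radius=5.0, target_bvf=3.0, seed=1)
        expected = round(0.03 * 248.0**2 / (math.pi * 25.0))
        assert expected <= v.meta["n_disks"] <= expected + 5
        assert abs(v.bvf - 3.0) <= bvf_tolerance(3.0)

    def test_unreachable_target_names_range(self):
        with pytest.raises(ValueError, match="achievable|below"):
            make_disk_voxel(GRID_2D, radius=60.0, target_bvf=0.5, seed=0)

    def test_rejects_3d_grid(self):
        with pytest.raises(ValueError, match="2D"):
            make_disk_voxel(GridSpec((8, 8, 8), (2, 2, 2)), 5.0, 3.0)


class TestCylinders:
    def test_zero_target(self):
        g = GridSpec((16, 16, 24), (3.875,) * 3)
        v = make_cylinder_voxel(g, fixed_radius(5.0), 0.0, seed=0)
        assert v.bvf == 0.0

    def test_axis_aligned_cylinder_volume(self):
        # single cylinder along z spanning the box: bvf = 100*pi*r^2/(Lx*Ly)
        g = GridSpec((124, 124, 93), (2.0, 2.0, 8.0))
        mask = _cylinder_mask(g, np.array([124.0, 124.0, 0.0]),
                              np.array([0.0, 0.0, 1.0]), 10.0)
        analytic = 100.0 * math.pi * 100.0 / (248.0 * 248.0)
        assert measure_bvf(mask) == pytest.approx(analytic, rel=0.1)

    def test_orientation_distribution_is_isotropic(self):
        rng = np.random.default_rng(42)
        u = sample_isotropic_directions(10_000, rng)
        assert np.allclose(np.linalg.norm(u, axis=1), 1.0)
        # equal-area bins: uniform cos(theta) x uniform phi
        zbin = np.digitize(u[:, 2], np.linspace(-1, 1, 11)[1:-1])
        pbin = np.digitize(np.arctan2(u[:, 1], u[:, 0]),
                           np.linspace(-np.pi, np.pi, 9)[1:-1])
        counts = np.bincount(zbin * 8 + pbin, minlength=80)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_target_bvf_within_tolerance(self, grid3d_small):
        for seed in range(3):
            v = make_cylinder_voxel(grid3d_small, fixed_radius(4.0), 3.0,
                                    seed=seed)
            assert abs(v.bvf - 3.0) <= bvf_tolerance(3.0)
            assert v.vessel_labels.max() >= 1

    def test_radius_exceeding_half_extent_fails(self, grid3d_small):
        with pytest.raises(ValueError, match="half-extent"):
            make_cylinder_voxel(grid3d_small, fixed_radius(60.0), 3.0)


class TestNetwork:
    def test_deterministic_given_seed(self, grid3d_small):
        p = NetworkParams(target_bvf=3.0, radius_law=fixed_radius(4.0), seed=5)
        a = grow_network_voxel(grid3d_small, p)
        b = grow_network_voxel(grid3d_small, p)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.vessel_labels, b.vessel_labels)

    def test_ensemble_covers_physiological_ranges(self):
        # the generator should emulate microscopy-derived voxels: BVf within
        # [0.5, 25] % and mean radius within [2, 12] µm over an ensemble
        grid = GridSpec((24, 24, 36), (3.875,) * 3)
        rng = np.random.default_rng(0)
        bvfs, radii = [], []
        for i in range(60):
            target = float(np.exp(rng.uniform(np.log(1.0), np.log(12.0))))
            r = float(np.exp(rng.uniform(np.log(3.0), np.log(8.0))))
            v = grow_network_voxel(
                grid, NetworkParams(target_bvf=target,
                                    radius_law=fixed_radius(r), seed=i))
            characterize_voxel(v)
            bvfs.append(v.bvf)
            radii.append(v.mean_radius)
        assert 0.5 <= min(bvfs) and max(bvfs) <= 25.0
        assert 2.0 <= min(radii) and max(radii) <= 12.0

    def test_zero_tortuosity_gives_straight_vessels(self, grid3d_small):
        p = NetworkParams(target_bvf=2.0, radius_law=fixed_radius(3.0),
                          tortuosity_scale=0.0, branching_rate=0.0, seed=1)
        v = grow_network_voxel(grid3d_small, p)
        for path_len, end_to_end in v.meta["paths"]:
            if path_len > 0:
                assert path_len / max(end_to_end, 1e-9) == pytest.approx(
                    1.0, rel=0.02)


class TestCharacterize:
    def test_all_ones_mask(self, grid3d_small):
        v = VoxelGeometry(grid3d_small, np.ones(grid3d_small.shape, bool))
        bvf, _ = characterize_voxel(v)
        assert bvf == 100.0

    def test_empty_mask_flags_radius(self, grid3d_small):
        v = VoxelGeometry(grid3d_small, np.zeros(grid3d_small.shape, bool))
        bvf, r = characterize_voxel(v)
        assert bvf == 0.0
        assert math.isnan(r)
        assert v.meta["radius_flag"] == "empty"

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_bvf_equals_occupancy_fraction(self, seed, p):
        rng = np.random.default_rng(seed)
        occ = rng.random((6, 6, 6)) < p
        g = GridSpec((6, 6, 6), (2, 2, 2))
        v = VoxelGeometry(g, occ)
        bvf, _ = characterize_voxel(v)
        assert bvf == 100.0 * np.count_nonzero(occ) / occ.size

    @pytest.mark.parametrize("tilt_deg", [0.0, 60.0])
    def test_min_feret_recovers_cylinder_radius(self, tilt_deg):
        # a tilted cylinder shows elliptical cross-sections; the minimum
        # Feret diameter is the short axis, i.e. the true diameter
        g = GridSpec((64, 64, 64), (2.0, 2.0, 2.0))
        t = math.radians(tilt_deg)
        axis = np.array([math.sin(t), 0.0, math.cos(t)])
        mask = _cylinder_mask(g, np.array([64.0, 64.0, 64.0]), axis, 10.0)
        v = VoxelGeometry(g, mask)
        _, r = characterize_voxel(v)
        assert abs(r - 10.0) <= 2.0  # one grid spacing

    def test_min_feret_of_square(self):
        pts = np.array([[0, 0], [4, 0], [0, 3], [4, 3]], float)
        assert min_feret_diameter(pts) == pytest.approx(3.0)


class TestErosion:
    def test_zero_steps_is_identity(self, grid3d_small):
        v = make_cylinder_voxel(grid3d_small, fixed_radius(5.0), 4.0, seed=2)
        e = erode_voxel(v, 0)
        assert np.array_equal(e.occupancy, v.occupancy)
        assert e.provenance == "eroded"

    def test_ball_erodes_one_cell_with_cross_element(self):
        n = 28
        g = GridSpec((n, n, n), (1.0, 1.0, 1.0))
        c = (np.arange(n) - n / 2 + 0.5)
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        d2 = X**2 + Y**2 + Z**2
        ball10 = d2 <= 10.0**2
        v = VoxelGeometry(g, ball10)
        eroded = erode_voxel(v, 1).occupancy
        # independent oracle: a cell survives iff all 6 neighbours are set
        oracle = ball10.copy()
        for ax in range(3):
            for s in (1, -1):
                oracle &= np.roll(ball10, s, axis=ax)
        assert np.array_equal(eroded, oracle)
        # and the result is (digitally) the radius-9 ball
        ball9 = d2 <= 9.0**2
        assert np.count_nonzero(eroded ^ ball9) / ball9.sum() < 0.05

    def test_bvf_monotone_in_steps(self, grid3d_small):
        p = NetworkParams(target_bvf=6.0, radius_law=fixed_radius(5.0), seed=3)
        v = grow_network_voxel(grid3d_small, p)
        prev = v.bvf
        for k in range(1, 4):
            e = erode_voxel(v, k)
            assert e.bvf <= prev + 1e-12
            prev = e.bvf

    def test_erosion_to_empty_is_flagged(self, grid3d_small):
        v = make_cylinder_voxel(grid3d_small, fixed_radius(4.0), 2.0, seed=0)
        e = erode_voxel(v, 10)
        assert e.bvf == 0.0
        assert e.meta.get("empty_after_erosion")
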