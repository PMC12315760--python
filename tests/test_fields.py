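"""Susceptibility maps and the Fourier dipole field solver."""

import numpy as np
import pytest

from vascmrf import GridSpec, SusceptibilityState, field_offset, field_offset_2d
from vascmrf.fields import GAMMA, susceptibility_map
from vascmrf.geometry import VoxelGeometry, fixed_radius, make_cylinder_voxel
from vascmrf.geometry import _cylinder_mask


def perp_cylinder_setup(n=64, sp=2.0, r_cells=8):
    """Cylinder along y, B0 along z; returns grid, chi, radius."""
    g = GridSpec((n, n, n), (sp, sp, sp))
    X, Y, Z = g.cell_centers()
    L = g.physical_extent
    r = r_cells * sp
    d2 = (X - L[0] / 2) ** 2 + (Z - L[2] / 2) ** 2
    chi = np.where(d2 <= r * r, 1.0, 0.0) * np.ones_like(Y)
    return g, chi, r


class TestSusceptibilityMap:
    def test_fully_oxygenated_no_contrast_is_zero(self, grid3d_small):
        v = make_cylinder_voxel(grid3d_small, fixed_radius(5.0), 3.0, seed=0)
        chi = susceptibility_map(v, SusceptibilityState(so2=100.0))
        assert np.all(chi == 0.0)

    def test_intravascular_formula(self, grid3d_small):
        v = make_cylinder_voxel(grid3d_small, fixed_radius(5.0), 3.0, seed=0)
        s = SusceptibilityState(so2=35.0, hct=0.42, dchi_deoxy=3.318,
                                dchi_ca=0.2)
        chi = susceptibility_map(v, s)
        expected = 3.318 * 0.42 * 0.65 + 0.2
        assert chi[v.occupancy] == pytest.approx(expected)
        assert np.all(chi[~v.occupancy] == 0.0)

    def test_distributed_mode_uniform_equals_single(self, grid3d_small):
        v = make_cylinder_voxel(grid3d_small, fixed_radius(5.0), 4.0, seed=1)
        labels = np.unique(v.vessel_labels[v.occupancy])
        uniform = susceptibility_map(v, SusceptibilityState(so2=60.0))
        distributed = susceptibility_map(
            v, SusceptibilityState(so2=60.0,
                                   per_vessel_so2={int(l): 60.0
                                                   for l in labels}))
        assert np.array_equal(uniform, distributed)

    def test_distributed_mode_missing_label_fails(self, grid3d_small):
        v = make_cylinder_voxel(grid3d_small, fixed_radius(5.0), 4.0, seed=1)
        with pytest.raises(ValueError, match="missing labels"):
            susceptibility_map(v, SusceptibilityState(so2=60.0,
                                                      per_vessel_so2={}))


class TestFieldSolver:
    def test_uniform_chi_gives_flat_field(self):
        g = GridSpec((8, 8, 8), (2, 2, 2))
        fm = field_offset(np.full(g.shape, 0.7), g)
        # k=0 convention: the uniform offset is absorbed into the frame
        assert np.allclose(fm.db, 0.0, atol=1e-9)

    def test_linearity_and_scaling(self):
        g = GridSpec((12, 12, 12), (2, 2, 2))
        rng = np.random.default_rng(0)
        c1, c2 = rng.random(g.shape), rng.random(g.shape)
        f1 = field_offset(c1, g).db
        f2 = field_offset(c2, g).db
        f12 = field_offset(2.0 * c1 + 3.0 * c2, g).db
        assert np.allclose(f12, 2.0 * f1 + 3.0 * f2, atol=1e-6)
        assert np.allclose(field_offset(c1, g, b0=9.4).db, 2.0 * f1,
                           rtol=1e-12)

    def test_perpendicular_cylinder_matches_closed_form(self):
        # closed-form 2D dipole of the cylinder and its periodic images
        # (on a 64-cell box the nearest images contribute measurably)
        g, chi, r = perp_cylinder_setup()
        fm = field_offset(chi, g, b0=4.7, b0_axis=(0, 0, 1))
        X, Y, Z = g.cell_centers()
        L = g.physical_extent
        j = g.shape[1] // 2
        x = X[:, 0, 0] - L[0] / 2
        z = Z[0, 0, :] - L[2] / 2
        XX, ZZ = np.meshgrid(x, z, indexing="ij")
        w0 = GAMMA * 4.7 * 1e-6
        exact = np.zeros_like(XX)
        for ix in range(-2, 3):
            for iz in range(-2, 3):
                dx = XX - ix * L[0]
                dz = ZZ - iz * L[2]
                rho2 = dx * dx + dz * dz
                # (r/rho)^2 cos 2phi with phi measured from B0 (z)
                exact += 0.5 * w0 * r * r * (dz * dz - dx * dx) / rho2**2
        rho = np.hypot(XX, ZZ)
        sim = fm.db[:, j, :]
        ring = (rho >= 2 * r) & (rho <= 3.2 * r)
        # the solver's zero-mean convention shifts the field by a constant
        offset = np.median(sim[ring] - exact[ring])
        envelope = 0.5 * w0 * (r / rho[ring]) ** 2
        err = np.abs(sim[ring] - offset - exact[ring]) / envelope
        assert err.max() < 0.05

    def test_parallel_cylinder_exterior_vanishes(self):
        n, sp, rc = 64, 2.0, 8
        g = GridSpec((n, n, n), (sp, sp, sp))
        X, Y, Z = g.cell_centers()
        L = g.physical_extent
        r = rc * sp
        d2 = (X - L[0] / 2) ** 2 + (Y - L[1] / 2) ** 2
        chi = np.where(d2 <= r * r, 1.0, 0.0) * np.ones_like(Z)
        fm = field_offset(chi, g, b0_axis=(0, 0, 1))
        rho3 = np.broadcast_to(np.sqrt(d2), fm.db.shape)
        interior = fm.db[rho3 <= 0.7 * r].mean()
        exterior = fm.db[rho3 >= 2 * r]
        leak = np.abs(exterior - np.median(exterior)) / abs(interior)
        assert leak.max() < 0.01

    def test_rotation_consistency(self):
        # cylinder along z with B0 along x == cylinder along x with B0
        # along z: the field histograms must agree up to rasterization
        n = 32
        g = GridSpec((n, n, n), (2, 2, 2))
        X, Y, Z = g.cell_centers()
        L = g.physical_extent
        r = 12.0
        chi_z = (((X - L[0] / 2) ** 2 + (Y - L[1] / 2) ** 2 <= r * r)
                 * np.ones_like(Z)).astype(float)
        chi_x = (((Y - L[1] / 2) ** 2 + (Z - L[2] / 2) ** 2 <= r * r)
                 * np.ones_like(X)).astype(float)
        f1 = np.sort(field_offset(chi_z, g, b0_axis=(1, 0, 0)).db.ravel())
        f2 = np.sort(field_offset(chi_x, g, b0_axis=(0, 0, 1)).db.ravel())
        scale = np.abs(f1).max()
        assert np.abs(f1 - f2).max() / scale < 0.05

    def test_zero_dims_rejected(self):
        g = GridSpec((8, 8, 8), (2, 2, 2))
        with pytest.raises(ValueError):
            field_offset(np.ones((4, 4, 4)), g)


class Test2DSolver:
    def test_uniform_chi_constant(self, grid2d):
        fm = field_offset_2d(np.full(grid2d.shape, 1.0), grid2d)
        assert np.allclose(fm.db, 0.0, atol=1e-9)

    def test_3d_input_fails(self):
        g = GridSpec((8, 8, 8), (2, 2, 2))
        with pytest.raises(ValueError):
            field_offset_2d(np.ones(g.shape), g)

    def test_disk_matches_perpendicular_cylinder_form(self):
        # a disk in the plane is the cross-section of a cylinder
        # perpendicular to B0 (B0 in-plane along x)
        n, sp = 128, 2.0
        g = GridSpec((n, n, 1), (sp, sp, sp))
        X, Y, _ = g.cell_centers()
        L = g.physical_extent
        r = 8 * sp
        d2 = (X - L[0] / 2) ** 2 + (Y - L[1] / 2) ** 2
        chi = np.where(d2 <= r * r, 1.0, 0.0)
        fm = field_offset_2d(chi, g, b0=4.7, b0_angle=0.0)
        rho = np.sqrt(d2)[:, :, 0]
        phi = np.arctan2((Y - L[1] / 2), (X - L[0] / 2))[:, :, 0]
        w0 = GAMMA * 4.7 * 1e-6
        exact = 0.5 * w0 * (r / rho) ** 2 * np.cos(2 * phi)
        sim = fm.db[:, :, 0]
        ring = (rho >= 2 * r) & (rho <= 3.2 * r)
        offset = np.median(sim[ring] - exact[ring])
        envelope = 0.5 * w0 * (r / rho[ring]) ** 2
        assert (np.abs(sim[ring] - offset - exact[ring]) / envelope).max() < 0.05

    def test_linearity(self, grid2d):
        rng = np.random.default_rng(1)
        c1 = rng.random(grid2d.shape)
        c2 = rng.random(grid2d.shape)
        f = field_offset_2d
        assert np.allclose(f(3 * c1 - c2, grid2d).db,
                           3 * f(c1, grid2d).db - f(c2, grid2d).db,
                           atol=1e-6)
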