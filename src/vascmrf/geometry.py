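"""Voxel-scale vascular geometry generation and characterization.

An "MRI-sized voxel" is represented as a binary occupancy volume on a
micrometre-resolution :class:`~vascmrf.grid.GridSpec` (1 = intravascular).
Three generator families are provided, mirroring the three dictionary
families used for vascular fingerprinting:

* 2D voxels containing disks of a single radius (``disk2d``),
* 3D voxels containing straight cylinders with isotropically distributed
  orientations and variable radii (``cylinder3d``),
* stochastic tortuous branching networks standing in for voxels extracted
  from whole-brain microscopy (``network3d``).

Shapes are rasterized with periodic wrap (minimum-image distance), which
matches the periodic FFT field solver, and may overlap; occupancy is the
union. Voxels are characterized by their blood volume fraction (BVf, % of
occupied cells) and mean vessel radius, the latter measured as half the mean
minimum Feret diameter of per-slice 2D vessel cross-sections so that tilted
vessels report their true radius (the short axis of the observed ellipse)
rather than an elongated cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .grid import GridSpec

__all__ = [
    "VoxelGeometry",
    "NetworkParams",
    "measure_bvf",
    "bvf_tolerance",
    "fixed_radius",
    "uniform_radius",
    "loguniform_radius",
    "sample_isotropic_directions",
    "make_disk_voxel",
    "make_cylinder_voxel",
    "grow_network_voxel",
    "characterize_voxel",
    "erode_voxel",
    "min_feret_diameter",
]

RadiusLaw = Union[float, Callable[[np.random.Generator], float]]


@dataclass
class VoxelGeometry:
    """Binary vessel occupancy volume with derived descriptors."""

    grid: GridSpec
    occupancy: np.ndarray
    vessel_labels: Optional[np.ndarray] = None
    bvf: float = 0.0
    mean_radius: float = float("nan")
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid {self.grid.shape}"
            )
        self.occupancy = occ
        if self.vessel_labels is not None:
            lab = np.asarray(self.vessel_labels)
            if lab.shape != occ.shape:
                raise ValueError("vessel_labels shape does not match occupancy")
            self.vessel_labels = lab.astype(np.int32)

    @property
    def n_vessels(self) -> int:
        if self.vessel_labels is None:
            return 0
        return int(self.vessel_labels.max())


@dataclass
class NetworkParams:
    """Controls for the stochastic vascular network generator."""

    target_bvf: float
    radius_law: RadiusLaw = (2.0, 12.0)
    branching_rate: float = 0.08
    tortuosity_scale: float = 0.35
    segment_length_law: tuple[float, float] = (40.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_bvf < 100.0:
            raise ValueError("target_bvf must be in (0, 100)")


def measure_bvf(occupancy: np.ndarray) -> float:
    """Blood volume fraction in percent: 100 × occupied cells / total cells."""
    occ = np.asarray(occupancy, dtype=bool)
    return 100.0 * float(np.count_nonzero(occ)) / occ.size


def bvf_tolerance(target_bvf: float) -> float:
    """Generator acceptance band: max(0.05 percentage points, 2% relative)."""
    return max(0.05, 0.02 * target_bvf)


# ---------------------------------------------------------------------------
# radius laws


def fixed_radius(r: float) -> Callable[[np.random.Generator], float]:
    return lambda rng: float(r)


def uniform_radius(lo: float, hi: float) -> Callable[[np.random.Generator], float]:
    return lambda rng: float(rng.uniform(lo, hi))


def loguniform_radius(lo: float, hi: float) -> Callable[[np.random.Generator], float]:
    llo, lhi = math.log(lo), math.log(hi)
    return lambda rng: float(math.exp(rng.uniform(llo, lhi)))


def _draw_radius(law: RadiusLaw, rng: np.random.Generator) -> float:
    if callable(law):
        r = float(law(rng))
    elif np.isscalar(law):
        r = float(law)
    elif hasattr(law, "rvs"):
        r = float(law.rvs(random_state=rng))
    else:
        lo, hi = law
        r = float(rng.uniform(lo, hi))
    if r <= 0:
        raise ValueError(f"radius law produced a non-positive radius {r}")
    return r


def sample_isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the sphere, shape (n, 3)."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # resample the (measure-zero) degenerate draws
    bad = norms[:, 0] < 1e-12
    while np.any(bad):
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        bad = norms[:, 0] < 1e-12
    return v / norms


# ---------------------------------------------------------------------------
# rasterization helpers (periodic, minimum-image)


def _wrapped_delta(coord, origin, extent):
    d = coord - origin
    return d - extent * np.round(d / extent)


try:
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _cyl_raster(out, shape, spacing, L, p, u, r2, clamp_len):
        nx, ny, nz = shape
        for i in range(nx):
            dx = (i + 0.5) * spacing[0] - p[0]
            dx -= L[0] * np.round(dx / L[0])
            for j in range(ny):
                dy = (j + 0.5) * spacing[1] - p[1]
                dy -= L[1] * np.round(dy / L[1])
                for k in range(nz):
                    dz = (k + 0.5) * spacing[2] - p[2]
                    dz -= L[2] * np.round(dz / L[2])
                    t = dx * u[0] + dy * u[1] + dz * u[2]
                    if clamp_len >= 0.0:
                        if t < 0.0:
                            t = 0.0
                        elif t > clamp_len:
                            t = clamp_len
                    ex = dx - t * u[0]
                    ey = dy - t * u[1]
                    ez = dz - t * u[2]
                    out[i, j, k] = ex * ex + ey * ey + ez * ez <= r2

    _HAVE_NUMBA_RASTER = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA_RASTER = False


def _disk_mask(grid: GridSpec, center: np.ndarray, radius: float) -> np.ndarray:
    (X, Y, _) = grid.cell_centers()
    Lx, Ly, _ = grid.physical_extent
    dx = _wrapped_delta(X, center[0], Lx)
    dy = _wrapped_delta(Y, center[1], Ly)
    return (dx * dx + dy * dy) <= radius * radius


def _cylinder_mask(grid: GridSpec, point: np.ndarray, axis: np.ndarray,
                   radius: float) -> np.ndarray:
    """Cells within ``radius`` of the nearest periodic image of an infinite line."""
    if _HAVE_NUMBA_RASTER:
        out = np.empty(grid.shape, dtype=np.bool_)
        _cyl_raster(out, np.asarray(grid.shape, np.int64),
                    np.asarray(grid.spacing), np.asarray(grid.physical_extent),
                    np.asarray(point, np.float64),
                    np.asarray(axis, np.float64),
                    float(radius) ** 2, -1.0)
        return out
    X, Y, Z = grid.cell_centers()
    L = grid.physical_extent
    dx = _wrapped_delta(X, point[0], L[0])
    dy = _wrapped_delta(Y, point[1], L[1])
    dz = _wrapped_delta(Z, point[2], L[2])
    t = dx * axis[0] + dy * axis[1] + dz * axis[2]
    d2 = (dx - t * axis[0]) ** 2 + (dy - t * axis[1]) ** 2 + (dz - t * axis[2]) ** 2
    return d2 <= radius * radius


def _raster_segment(occ: np.ndarray, labels: np.ndarray, grid: GridSpec,
                    p0: np.ndarray, p1: np.ndarray, radius: float,
                    label: int) -> None:
    """Rasterize a capsule (cylinder with hemispherical caps) in-place.

    Only the bounding subgrid is visited; indices wrap periodically.
    """
    sp = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)
    lo = np.minimum(p0, p1) - radius - sp
    hi = np.maximum(p0, p1) + radius + sp
    idx = []
    for ax in range(3):
        i0 = int(np.floor(lo[ax] / sp[ax]))
        i1 = int(np.ceil(hi[ax] / sp[ax]))
        n = shape[ax]
        if i1 - i0 >= n:
            ids = np.arange(n)
        else:
            ids = np.arange(i0, i1 + 1) % n
        idx.append(ids)
    coords = [(idx[ax].astype(float) + 0.5) * sp[ax] for ax in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij", sparse=True)
    L = grid.physical_extent
    u = p1 - p0
    seg_len = float(np.linalg.norm(u))
    if seg_len < 1e-12:
        u = np.zeros(3)
        seg_len = 0.0
    else:
        u = u / seg_len
    dx = _wrapped_delta(X, p0[0], L[0])
    dy = _wrapped_delta(Y, p0[1], L[1])
    dz = _wrapped_delta(Z, p0[2], L[2])
    t = np.clip(dx * u[0] + dy * u[1] + dz * u[2], 0.0, seg_len)
    d2 = (dx - t * u[0]) ** 2 + (dy - t * u[1]) ** 2 + (dz - t * u[2]) ** 2
    inside = d2 <= radius * radius
    sub = np.ix_(idx[0], idx[1], idx[2])
    new = inside & ~occ[sub]
    occ[sub] |= inside
    if labels is not None:
        lab_sub = labels[sub]
        lab_sub[new] = label
        labels[sub] = lab_sub


# ---------------------------------------------------------------------------
# generators


def _fill_to_target(grid: GridSpec, target_bvf: float, draw_mask, seed: int,
                    max_rejects: int = 60, what: str = "structure",
                    tuner=None):
    """Shared accept/reject loop: add structures until bvf is within tolerance.

    ``draw_mask(rng) -> (mask, meta)`` proposes one structure. Overshooting
    proposals are rejected and redrawn; once random draws keep overshooting
    (the remaining gap is smaller than one structure), the optional
    ``tuner(rng, occ, structures, lo, hi)`` is asked to place a final
    partially-overlapping structure whose marginal volume lands the realized
    BVf inside [lo, hi] (implemented by bisecting the lateral offset from an
    existing structure — the marginal volume varies continuously with it).
    """
    rng = np.random.default_rng(seed)
    occ = np.zeros(grid.shape, dtype=bool)
    labels = np.zeros(grid.shape, dtype=np.int32)
    tol = bvf_tolerance(target_bvf)
    lo, hi = target_bvf - tol, target_bvf + tol
    bvf = 0.0
    rejects = 0
    structures = []
    while bvf < lo:
        mask = meta = None
        if rejects >= 10 and tuner is not None and structures:
            mask, meta = tuner(rng, occ, structures, lo, hi) or (None, None)
        if mask is None:
            mask, meta = draw_mask(rng)
        cand = occ | mask
        cand_bvf = measure_bvf(cand)
        if cand_bvf > hi:
            rejects += 1
            if rejects > max_rejects:
                raise ValueError(
                    f"cannot reach target_bvf={target_bvf:.3g}% within "
                    f"tolerance ±{tol:.3g} pp by adding one more {what}: "
                    f"achievable neighbourhood is [{bvf:.3g}, "
                    f"{cand_bvf:.3g}]% with the given radii and grid"
                )
            continue
        rejects = 0
        new = mask & ~occ
        occ = cand
        labels[new] = len(structures) + 1
        structures.append(meta)
        bvf = cand_bvf
    return occ, labels, bvf, structures


def _bisect_offset(occ, make_mask, lo, hi, t_max, n_iter=30):
    """Find offset t so that bvf(occ | mask(t)) lands in [lo, hi].

    ``make_mask(t)`` must give a marginal volume (weakly) increasing in t.
    Returns the mask or None when the window is not bracketed.
    """
    f_lo = measure_bvf(occ | make_mask(0.0))
    f_hi = measure_bvf(occ | make_mask(t_max))
    if f_lo > hi or f_hi < lo:
        return None
    a, b = 0.0, t_max
    for _ in range(n_iter):
        t = 0.5 * (a + b)
        mask = make_mask(t)
        v = measure_bvf(occ | mask)
        if v < lo:
            a = t
        elif v > hi:
            b = t
        else:
            return mask
    return None


def make_disk_voxel(grid: GridSpec, radius: float, target_bvf: float,
                    seed: int = 0) -> VoxelGeometry:
    """2D voxel filled with disks of a single radius at random centres.

    Disks are placed uniformly at random with periodic wrap and may overlap
    (occupancy is the union); disks are added until the realized BVf lies
    within ``max(0.05 pp, 2% relative)`` of ``target_bvf``.
    """
    if not grid.is_2d:
        raise ValueError("make_disk_voxel requires a 2D grid (nz = 1)")
    Lx, Ly, _ = grid.physical_extent
    if radius <= 0:
        raise ValueError("radius must be positive")
    one_disk = 100.0 * math.pi * radius**2 / (Lx * Ly)
    if one_disk >= 100.0:
        raise ValueError(
            f"a single disk of radius {radius} µm covers {one_disk:.1f}% of the "
            f"{Lx}×{Ly} µm plane; achievable targets are below 100%"
        )
    if target_bvf == 0:
        return VoxelGeometry(grid, np.zeros(grid.shape, bool),
                             np.zeros(grid.shape, np.int32), 0.0,
                             float("nan"), "disk2d")
    tol = bvf_tolerance(target_bvf)
    if target_bvf + tol < one_disk * 0.5:
        raise ValueError(
            f"target_bvf={target_bvf:.3g}% is below the smallest achievable "
            f"non-empty BVf (~one disk = {one_disk:.3g}%)"
        )

    def draw(rng):
        c = rng.uniform([0, 0], [Lx, Ly])
        return _disk_mask(grid, c, radius), {"center": c, "radius": radius}

    def tune(rng, occ, structures, lo, hi):
        anchor = structures[rng.integers(len(structures))]["center"]
        theta = rng.uniform(0, 2 * math.pi)
        u = np.array([math.cos(theta), math.sin(theta)])

        def make_mask(t):
            return _disk_mask(grid, anchor + t * u, radius)

        mask = _bisect_offset(occ, make_mask, lo, hi,
                              2 * radius + 2 * max(grid.spacing[:2]))
        if mask is None:
            return None
        return mask, {"center": anchor, "radius": radius, "tuned": True}

    occ, labels, bvf, structs = _fill_to_target(grid, target_bvf, draw, seed,
                                                what="disk", tuner=tune)
    return VoxelGeometry(grid, occ, labels, bvf, float("nan"), "disk2d",
                         meta={"radius": radius, "n_disks": len(structs),
                               "target_bvf": target_bvf, "seed": seed})


def make_cylinder_voxel(grid: GridSpec, radius_law: RadiusLaw,
                        target_bvf: float, seed: int = 0) -> VoxelGeometry:
    """3D voxel filled with straight cylinders, isotropically oriented.

    Radii are drawn from ``radius_law`` (a scalar, a ``(lo, hi)`` uniform
    range, a frozen scipy distribution, or a callable of an rng); axes are
    uniform on the sphere; positions uniform in the box; rasterization uses
    the minimum-image distance to the cylinder axis (periodic wrap).
    """
    if grid.is_2d:
        raise ValueError("make_cylinder_voxel requires a 3D grid")
    L = grid.physical_extent
    half_extent = min(L) / 2.0
    if target_bvf == 0:
        return VoxelGeometry(grid, np.zeros(grid.shape, bool),
                             np.zeros(grid.shape, np.int32), 0.0,
                             float("nan"), "cylinder3d")

    def draw(rng):
        r = _draw_radius(radius_law, rng)
        if r > half_extent:
            raise ValueError(
                f"radius {r:.3g} µm exceeds the grid half-extent "
                f"{half_extent:.3g} µm"
            )
        axis = sample_isotropic_directions(1, rng)[0]
        p = rng.uniform([0, 0, 0], list(L))
        return (_cylinder_mask(grid, p, axis, r),
                {"point": p, "axis": axis, "radius": r})

    def tune(rng, occ, structures, lo, hi):
        # final cylinder: same axis as an existing one, lateral offset
        # bisected so its marginal volume closes the remaining gap
        s = structures[rng.integers(len(structures))]
        axis, p0, r = s["axis"], s["point"], s["radius"]
        perp = np.cross(axis, sample_isotropic_directions(1, rng)[0])
        n = np.linalg.norm(perp)
        if n < 1e-6:
            return None
        perp = perp / n

        def make_mask(t):
            return _cylinder_mask(grid, p0 + t * perp, axis, r)

        mask = _bisect_offset(occ, make_mask, lo, hi,
                              2 * r + 2 * max(grid.spacing))
        if mask is None:
            return None
        return mask, {"point": p0, "axis": axis, "radius": r, "tuned": True}

    occ, labels, bvf, structs = _fill_to_target(grid, target_bvf, draw, seed,
                                                what="cylinder", tuner=tune)
    return VoxelGeometry(grid, occ, labels, bvf, float("nan"), "cylinder3d",
                         meta={"n_cylinders": len(structs),
                               "radii": [s["radius"] for s in structs],
                               "target_bvf": target_bvf, "seed": seed})


def grow_network_voxel(grid: GridSpec, params: NetworkParams,
                       max_restarts: int = 5) -> VoxelGeometry:
    """Stochastic tortuous, branching tubular network.

    Vessels are grown as persistent random walks rasterized as capsule
    chains: each vessel starts at a uniform random point with an isotropic
    direction, marches in sub-steps, perturbing its direction with standard
    deviation ``tortuosity_scale`` (radians per ~10 µm of path), and may
    spawn a branch per sub-step with probability ``branching_rate``. Vessel
    radii come from ``radius_law``; per-vessel integer labels are recorded
    for the distributed-oxygenation mode. Vessels are added until the BVf
    tolerance band around ``target_bvf`` is reached.
    """
    if grid.is_2d:
        raise ValueError("grow_network_voxel requires a 3D grid")
    L = np.asarray(grid.physical_extent)
    ds = float(max(grid.spacing)) * 1.5
    tol = bvf_tolerance(params.target_bvf)

    for attempt in range(max_restarts):
        rng = np.random.default_rng(np.random.SeedSequence(
            (params.seed, attempt)))
        occ = np.zeros(grid.shape, dtype=bool)
        labels = np.zeros(grid.shape, dtype=np.int32)
        bvf = 0.0
        next_label = 1
        tortuosity = []
        rejects = 0
        while bvf < params.target_bvf - tol and rejects <= 200:
            # grow one vessel tree (trunk + spawned branches) on a copy
            occ_c = occ.copy()
            labels_c = labels.copy()
            queue = [(rng.uniform(np.zeros(3), L),
                      sample_isotropic_directions(1, rng)[0],
                      float(rng.uniform(*params.segment_length_law)),
                      _draw_radius(params.radius_law, rng))]
            lab = next_label
            tree_labels = 0
            tree_paths = []
            done = False
            while queue and not done:
                p, u, remaining, r = queue.pop()
                start = p.copy()
                path_len = 0.0
                this_label = lab + tree_labels
                tree_labels += 1
                while remaining > 0:
                    step = min(ds, remaining)
                    q = p + u * step
                    _raster_segment(occ_c, labels_c, grid, p, q, r, this_label)
                    path_len += step
                    # sub-step granularity lets growth stop inside the band
                    if measure_bvf(occ_c) >= params.target_bvf - tol:
                        done = True
                        p = q
                        break
                    if params.tortuosity_scale > 0:
                        kick = (params.tortuosity_scale
                                * math.sqrt(step / 10.0)
                                * rng.standard_normal(3))
                        u = u + kick
                        u = u / np.linalg.norm(u)
                    if (params.branching_rate > 0
                            and rng.uniform() < params.branching_rate
                            and tree_labels < 64):
                        bdir = u + 0.8 * rng.standard_normal(3)
                        bdir = bdir / np.linalg.norm(bdir)
                        queue.append((q.copy(), bdir, remaining * 0.7,
                                      max(r * 0.75, 1.0)))
                    p = q
                    remaining -= step
                end_to_end = float(np.linalg.norm(p - start))
                tree_paths.append((path_len, end_to_end))
            cand_bvf = measure_bvf(occ_c)
            if cand_bvf > params.target_bvf + tol:
                rejects += 1
                continue
            occ, labels = occ_c, labels_c
            bvf = cand_bvf
            next_label = lab + tree_labels
            tortuosity.extend(tree_paths)
            rejects = 0
        if params.target_bvf - tol <= bvf <= params.target_bvf + tol:
            return VoxelGeometry(
                grid, occ, labels, bvf, float("nan"), "network3d",
                meta={"target_bvf": params.target_bvf, "seed": params.seed,
                      "n_vessels": next_label - 1, "paths": tortuosity})
    raise RuntimeError(
        f"network growth failed to reach BVf {params.target_bvf:.3g}% "
        f"(±{tol:.3g} pp) after {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# characterization


def min_feret_diameter(points: np.ndarray) -> float:
    """Minimum caliper width of a 2D point cloud (rotating calipers on hull)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        span = pts.max(axis=0) - pts.min(axis=0)
        return float(np.linalg.norm(span))
    try:
        hull = ConvexHull(pts)
    except QhullError:
        span = pts.max(axis=0) - pts.min(axis=0)
        return float(min(span[span > 0], default=0.0))
    v = pts[hull.vertices]
    edges = np.roll(v, -1, axis=0) - v
    lens = np.linalg.norm(edges, axis=1)
    good = lens > 1e-12
    normals = np.stack([-edges[good, 1], edges[good, 0]], axis=1) / lens[good, None]
    # width along each edge normal; the minimum width is attained on an edge
    proj = normals @ v.T
    widths = proj.max(axis=1) - proj.min(axis=1)
    return float(widths.min())


def _slice_detections(occ2d: np.ndarray, spacing_xy: tuple[float, float],
                      min_area: int) -> list[float]:
    lab, n = ndi.label(occ2d)
    out = []
    if n == 0:
        return out
    objects = ndi.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        comp = lab[sl] == i
        area = int(comp.sum())
        if area < min_area:
            continue
        ii, jj = np.nonzero(comp)
        ii = ii + sl[0].start
        jj = jj + sl[1].start
        # pixel corners, in micrometres, so the caliper sees pixel extent
        base = np.stack([ii * spacing_xy[0], jj * spacing_xy[1]], axis=1)
        corners = np.concatenate([
            base,
            base + [spacing_xy[0], 0.0],
            base + [0.0, spacing_xy[1]],
            base + [spacing_xy[0], spacing_xy[1]],
        ])
        out.append(min_feret_diameter(corners))
    return out


def characterize_voxel(v: VoxelGeometry, min_area: int = 5,
                       slice_stride: Optional[int] = None) -> tuple[float, float]:
    """Measure (BVf %, mean vessel radius µm) and store them on the geometry.

    BVf is exact voxel counting. The radius is half the mean minimum Feret
    diameter of 2D connected components detected in xy-slices (components
    smaller than ``min_area`` cells are treated as rasterization noise; if
    nothing passes the filter the measurement falls back to all components
    and flags it in ``meta``). By default at most ~24 evenly spaced slices
    are measured — the per-slice detections are statistically exchangeable,
    so subsampling leaves the mean unchanged.
    """
    v.bvf = measure_bvf(v.occupancy)
    sp = v.grid.spacing[:2]
    if v.bvf == 0.0:
        v.mean_radius = float("nan")
        v.meta["radius_flag"] = "empty"
        return v.bvf, v.mean_radius
    nz = v.grid.shape[2]
    if slice_stride is None:
        slice_stride = max(1, nz // 24)
    diam: list[float] = []
    for k in range(0, nz, slice_stride):
        diam.extend(_slice_detections(v.occupancy[:, :, k], sp, min_area))
    flag = ""
    if not diam:
        flag = "min_area_fallback"
        for k in range(0, nz, slice_stride):
            diam.extend(_slice_detections(v.occupancy[:, :, k], sp, 1))
    if not diam:
        v.mean_radius = float("nan")
        v.meta["radius_flag"] = "no_detections"
        return v.bvf, v.mean_radius
    v.mean_radius = 0.5 * float(np.mean(diam))
    if flag:
        v.meta["radius_flag"] = flag
    return v.bvf, v.mean_radius


def erode_voxel(v: VoxelGeometry, steps: int) -> VoxelGeometry:
    """Morphological erosion with a 6-connected (3D cross) element, periodic.

    ``steps = 0`` returns an identical copy. BVf is non-increasing in
    ``steps``; erosion to an empty mask is legal and flagged in ``meta``.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    occ = v.occupancy
    if steps > 0:
        rank = 2 if v.grid.is_2d else 3
        structure = ndi.generate_binary_structure(rank, 1)
        work = occ[:, :, 0] if v.grid.is_2d else occ
        pad = np.pad(work, steps, mode="wrap")
        pad = ndi.binary_erosion(pad, structure=structure, iterations=steps)
        sl = tuple(slice(steps, -steps) for _ in range(rank))
        work = pad[sl]
        occ = work[:, :, None] if v.grid.is_2d else work
    labels = None
    if v.vessel_labels is not None:
        labels = np.where(occ, v.vessel_labels, 0).astype(np.int32)
    out = VoxelGeometry(v.grid, occ.copy(), labels, measure_bvf(occ),
                        float("nan"), "eroded",
                        meta={"parent": v.provenance, "steps": steps})
    if out.bvf == 0.0:
        out.meta["empty_after_erosion"] = True
    return out
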