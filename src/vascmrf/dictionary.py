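"""Fingerprint dictionary generation and persistence.

A dictionary is an aligned table of vascular parameter vectors
(BVf %, mean radius µm, SO2 %, T2 ms) and simulated, L2-normalized
pre/post-contrast GESFIDSE fingerprints. Three families are supported,
differing only in the voxel geometry generator: 2D disks (``disk2d``), 3D
isotropically oriented cylinders (``cylinder3d``), and stochastic
realistic-like networks (``network3d``).

SO2 and T2 are sampled jointly from a scrambled 2D Sobol sequence over
[35, 90] % x [45, 110] ms — one draw per voxel geometry — while BVf and
radius are imposed by the geometry and recorded as measured on the
rasterized mask. Pre- and post-contrast states share one unit-susceptibility
field solve per geometry (the dipole field is linear in the uniform
intravascular susceptibility).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import __version__ as _pkg_version
from .fields import (DCHI_DEOXY_PPM, DEFAULT_DCHI_CA_PPM, DEFAULT_HCT,
                     SusceptibilityState, field_offset, field_offset_2d,
                     susceptibility_map)
from .geometry import (NetworkParams, VoxelGeometry, characterize_voxel,
                       fixed_radius, grow_network_voxel, make_cylinder_voxel,
                       make_disk_voxel)
from .gesfidse import SequenceSpec, SimPhysics, make_fingerprint, simulate_gesfidse
from .grid import GridSpec

__all__ = [
    "PhysicsConstants",
    "FingerprintDictionary",
    "sobol_sample",
    "sample_vascular_conditions",
    "geometries_from_conditions",
    "build_dictionary",
    "make_family_dictionary",
    "save_dictionary",
    "load_dictionary",
    "default_dictionary_grid",
    "SO2_RANGE",
    "T2_RANGE",
]

FORMAT_VERSION = 1

#: sampled parameter ranges: SO2 in percent, T2 in ms
SO2_RANGE = (35.0, 90.0)
T2_RANGE = (45.0, 110.0)

#: desk-scale vascular conditions for synthetic families
BVF_RANGE = (1.0, 12.0)
RADIUS_RANGE = (3.0, 10.0)


@dataclass(frozen=True)
class PhysicsConstants:
    """Fixed simulation physics shared by all dictionary entries."""

    b0: float = 4.7
    hct: float = DEFAULT_HCT
    dchi_deoxy_ppm: float = DCHI_DEOXY_PPM
    dchi_ca_ppm: float = DEFAULT_DCHI_CA_PPM
    adc: float = 1000.0
    b0_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    b0_angle_2d: float = 0.0


@dataclass
class FingerprintDictionary:
    """Aligned parameters and fingerprints plus provenance metadata."""

    params: pd.DataFrame
    signals: np.ndarray
    norms: np.ndarray
    meta: dict = field(default_factory=dict)

    PARAM_COLUMNS = ("bvf", "radius", "so2", "t2", "voxel_id")

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.norms = np.asarray(self.norms, dtype=np.float64)
        if len(self.params) != len(self.signals):
            raise ValueError(
                f"params has {len(self.params)} rows but signals has "
                f"{len(self.signals)}"
            )
        if len(self.norms) != len(self.signals):
            raise ValueError("norms length does not match signals")
        missing = set(self.PARAM_COLUMNS) - set(self.params.columns)
        if missing:
            raise ValueError(f"params is missing columns {sorted(missing)}")
        dup = self.params.duplicated(subset=["voxel_id", "so2", "t2"])
        if dup.any():
            raise ValueError("duplicate (voxel_id, so2, t2) triples")

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def signal_length(self) -> int:
        return self.signals.shape[1]

    def parameter_array(self) -> np.ndarray:
        """(n, 4) array in the canonical order bvf, radius, so2, t2."""
        return self.params[["bvf", "radius", "so2", "t2"]].to_numpy()


def sobol_sample(n: int, ranges: Optional[dict[str, tuple[float, float]]] = None,
                 seed: int = 0) -> pd.DataFrame:
    """Scrambled Sobol points scaled into per-parameter bounds.

    The parameters are sampled jointly (one scrambled Sobol series of
    dimension ``len(ranges)``); the first ``n`` points of the next power of
    two are returned so the draw is deterministic in ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = {"so2": SO2_RANGE, "t2": T2_RANGE}
    names = list(ranges.keys())
    lo = np.array([ranges[k][0] for k in names], dtype=float)
    hi = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(hi <= lo):
        raise ValueError(f"degenerate bounds in {ranges}")
    sampler = qmc.Sobol(d=len(names), scramble=True, seed=seed)
    m = max(0, int(np.ceil(np.log2(n))))
    pts = sampler.random_base2(m)[:n]
    return pd.DataFrame(qmc.scale(pts, lo, hi), columns=names)


def sample_vascular_conditions(n: int, seed: int = 0,
                               bvf_range: tuple[float, float] = BVF_RANGE,
                               radius_range: tuple[float, float] = RADIUS_RANGE,
                               ) -> pd.DataFrame:
    """Draw (target BVf, radius) pairs for synthetic voxel families.

    Both are log-uniform over their ranges — vascular densities and calibre
    distributions are right-skewed — and the radius is capped by the largest
    cylinder that can fit the target BVf in the box (otherwise low-BVf,
    large-R combinations are geometrically unreachable).
    """
    rng = np.random.default_rng(seed)
    bvf = np.exp(rng.uniform(np.log(bvf_range[0]), np.log(bvf_range[1]), n))
    radius = np.exp(rng.uniform(np.log(radius_range[0]),
                                np.log(radius_range[1]), n))
    return pd.DataFrame({"target_bvf": bvf, "radius": radius})


def _radius_cap(grid: GridSpec, target_bvf: float) -> float:
    L = grid.physical_extent
    volume = L[0] * L[1] * L[2]
    min_chord = min(L)
    return 0.95 * float(np.sqrt(target_bvf / 100.0 * volume
                                / (np.pi * min_chord)))


def geometries_from_conditions(family: str, grid: GridSpec,
                               conditions: pd.DataFrame, seed: int = 0,
                               ) -> list[VoxelGeometry]:
    """Generate one voxel geometry per (target_bvf, radius) row."""
    seeds = np.random.SeedSequence(seed).generate_state(len(conditions))
    out = []
    for i, row in enumerate(conditions.itertuples(index=False)):
        s = int(seeds[i] % (2**31))
        if family == "disk2d":
            v = make_disk_voxel(grid, row.radius, row.target_bvf, seed=s)
        elif family == "cylinder3d":
            r = min(row.radius, _radius_cap(grid, row.target_bvf))
            v = make_cylinder_voxel(grid, fixed_radius(r), row.target_bvf,
                                    seed=s)
        elif family == "network3d":
            r = min(row.radius, _radius_cap(grid, row.target_bvf))
            params = NetworkParams(target_bvf=row.target_bvf,
                                   radius_law=fixed_radius(r), seed=s)
            v = grow_network_voxel(grid, params)
        else:
            raise ValueError(f"unknown family {family!r}")
        characterize_voxel(v)
        out.append(v)
    return out


def _simulate_entry(v: VoxelGeometry, so2: float, t2: float,
                    seq: SequenceSpec, physics: PhysicsConstants,
                    dtype=np.complex64,
                    distributed_so2: Optional[dict[int, float]] = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pre/post-contrast signals for one voxel."""
    phys = SimPhysics(t2_ms=t2, adc=physics.adc)
    if distributed_so2 is None:
        # field is linear in the uniform intravascular susceptibility:
        # one unit solve, two scalings
        chi_unit = v.occupancy.astype(np.float64)
        if v.grid.is_2d:
            unit = field_offset_2d(chi_unit, v.grid, b0=physics.b0,
                                   b0_angle=physics.b0_angle_2d)
        else:
            unit = field_offset(chi_unit, v.grid, b0=physics.b0,
                                b0_axis=physics.b0_axis)
        base = SusceptibilityState(so2=so2, hct=physics.hct,
                                   dchi_deoxy=physics.dchi_deoxy_ppm)
        a_pre = base.intravascular_dchi()
        a_post = a_pre + physics.dchi_ca_ppm
        pre = simulate_gesfidse(unit.scaled(a_pre), phys, seq, dtype=dtype)
        post = simulate_gesfidse(unit.scaled(a_post), phys, seq, dtype=dtype)
        return pre, post
    signals = []
    for dchi_ca in (0.0, physics.dchi_ca_ppm):
        state = SusceptibilityState(so2=so2, hct=physics.hct,
                                    dchi_deoxy=physics.dchi_deoxy_ppm,
                                    dchi_ca=dchi_ca,
                                    per_vessel_so2=distributed_so2)
        chi = susceptibility_map(v, state)
        if v.grid.is_2d:
            fmap = field_offset_2d(chi, v.grid, b0=physics.b0,
                                   b0_angle=physics.b0_angle_2d)
        else:
            fmap = field_offset(chi, v.grid, b0=physics.b0,
                                b0_axis=physics.b0_axis)
        signals.append(simulate_gesfidse(fmap, phys, seq, dtype=dtype))
    return signals[0], signals[1]


def build_dictionary(geometries: Sequence[VoxelGeometry],
                     samples: pd.DataFrame,
                     seq: Optional[SequenceSpec] = None,
                     physics: Optional[PhysicsConstants] = None,
                     dtype=np.complex64,
                     meta: Optional[dict] = None) -> FingerprintDictionary:
    """Run the forward chain over a geometry set.

    ``samples`` must provide one (so2, t2) row per geometry. Each entry does
    a pre-contrast and a post-contrast field/signal simulation and stores
    the jointly normalized concatenated fingerprint; the parameter row
    records the geometry's measured BVf and radius with the sampled SO2/T2.
    """
    if seq is None:
        seq = SequenceSpec(dt_sim_ms=None)
    if physics is None:
        physics = PhysicsConstants()
    if len(samples) != len(geometries):
        raise ValueError(
            f"{len(geometries)} geometries but {len(samples)} samples; "
            "expected one (so2, t2) pair per geometry"
        )
    n = len(geometries)
    signals = np.empty((n, 2 * seq.n_echoes))
    norms = np.empty(n)
    rows = []
    for i, (v, row) in enumerate(zip(geometries, samples.itertuples(index=False))):
        if not np.isfinite(v.bvf) or (np.isnan(v.mean_radius) and v.bvf > 0):
            characterize_voxel(v)
        try:
            pre, post = _simulate_entry(v, row.so2, row.t2, seq, physics,
                                        dtype=dtype)
        except Exception as err:
            raise RuntimeError(f"simulation failed for voxel_id={i}: {err}") from err
        fp = make_fingerprint(pre, post)
        signals[i] = fp.values
        norms[i] = fp.norm
        rows.append({"bvf": v.bvf, "radius": v.mean_radius,
                     "so2": float(row.so2), "t2": float(row.t2),
                     "voxel_id": i})
    params = pd.DataFrame(rows)
    full_meta = {
        "sequence": asdict(seq),
        "physics": asdict(physics),
        "format_version": FORMAT_VERSION,
        "package_version": _pkg_version,
        "n_entries": n,
        "families": sorted({v.provenance for v in geometries}),
    }
    if meta:
        full_meta.update(meta)
    return FingerprintDictionary(params, signals, norms, full_meta)


def default_dictionary_grid(family: str) -> GridSpec:
    """Desk-scale simulation grids (3.875 µm isotropic cells)."""
    if family == "disk2d":
        return GridSpec((64, 64, 1), (3.875, 3.875, 3.875))
    return GridSpec((48, 48, 72), (3.875, 3.875, 3.875))


def make_family_dictionary(family: str, n: int, seed: int = 0,
                           grid: Optional[GridSpec] = None,
                           seq: Optional[SequenceSpec] = None,
                           physics: Optional[PhysicsConstants] = None,
                           conditions: Optional[pd.DataFrame] = None,
                           ) -> FingerprintDictionary:
    """Convenience builder: conditions -> geometries -> Sobol -> dictionary."""
    if grid is None:
        grid = default_dictionary_grid(family)
    ss = np.random.SeedSequence(seed)
    s_cond, s_geom, s_sobol = (int(s % (2**31)) for s in ss.generate_state(3))
    if conditions is None:
        conditions = sample_vascular_conditions(n, seed=s_cond)
    geoms = geometries_from_conditions(family, grid, conditions, seed=s_geom)
    samples = sobol_sample(len(geoms), seed=s_sobol)
    return build_dictionary(geoms, samples, seq=seq, physics=physics,
                            meta={"family": family, "seed": seed,
                                  "grid_shape": list(grid.shape),
                                  "grid_spacing": list(grid.spacing)})


# ---------------------------------------------------------------------------
# persistence


def save_dictionary(d: FingerprintDictionary, path) -> None:
    """Write a dictionary to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["meta_json"] = json.dumps(d.meta, default=str)
        f.attrs["param_columns"] = list(d.params.columns)
        f.create_dataset("params", data=d.params.to_numpy(dtype=np.float64))
        f.create_dataset("signals", data=d.signals)
        f.create_dataset("norms", data=d.norms)


def load_dictionary(path) -> FingerprintDictionary:
    """Load a dictionary, validating version and internal consistency."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported dictionary format version {version} "
                f"(expected {FORMAT_VERSION})"
            )
        for key in ("params", "signals", "norms"):
            if key not in f:
                raise ValueError(f"truncated dictionary file: missing {key!r}")
        cols = [c for c in f.attrs["param_columns"]]
        params = pd.DataFrame(f["params"][()], columns=cols)
        signals = f["signals"][()]
        norms = f["norms"][()]
        meta = json.loads(f.attrs["meta_json"])
    params["voxel_id"] = params["voxel_id"].astype(int)
    return FingerprintDictionary(params, signals, norms, meta)
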