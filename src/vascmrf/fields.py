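"""Susceptibility maps and the Fourier dipole-kernel field solver.

Vessels filled with partially deoxygenated blood (and, post-injection, an
iron-oxide contrast agent) differ in magnetic susceptibility from the
surrounding tissue. The induced static field offset is obtained by
multiplying the susceptibility distribution with the dipole kernel in the
Fourier domain,

    db(k) = gamma * B0 * (1/3 - kz^2/|k|^2) * chi(k),

with kz the component of k along the B0 axis and periodic boundary
conditions. The k = 0 term is set to zero: the spatially uniform offset is
absorbed into the rotating frame and is irrelevant for magnitude signals.
Field maps are stored as angular-frequency offsets in rad/s.

For 2D voxels (disks in a plane with B0 in-plane, modelling cross-sections
of cylinders perpendicular to the plane) the 2D kernel (1/2 - kb^2/|k|^2)
is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.fft as sfft

from .geometry import VoxelGeometry
from .grid import GridSpec

__all__ = [
    "GAMMA",
    "SusceptibilityState",
    "FieldMap",
    "susceptibility_map",
    "field_offset",
    "field_offset_2d",
    "vessel_field",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA = 2.675e8

#: susceptibility difference (SI, ppm) between fully deoxygenated and fully
#: oxygenated blood per unit haematocrit (4*pi*0.264 ppm cgs)
DCHI_DEOXY_PPM = 3.318

#: default haematocrit
DEFAULT_HCT = 0.42

#: default added intravascular susceptibility from the contrast agent (ppm),
#: chosen on the order of the mid-range deoxygenation contrast
DEFAULT_DCHI_CA_PPM = 0.5


@dataclass
class SusceptibilityState:
    """Intravascular susceptibility model of a voxel.

    ``so2`` is the blood oxygen saturation in percent; ``dchi_ca`` the added
    contrast-agent susceptibility (0 before injection). ``per_vessel_so2``
    optionally maps vessel labels to individual SO2 values (the
    distributed-oxygenation mode).
    """

    so2: float
    hct: float = DEFAULT_HCT
    dchi_deoxy: float = DCHI_DEOXY_PPM
    dchi_ca: float = 0.0
    per_vessel_so2: Optional[dict[int, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2 <= 100.0:
            raise ValueError(f"so2 must be in [0, 100], got {self.so2}")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hct must be in (0, 1), got {self.hct}")
        if self.dchi_ca < 0.0:
            raise ValueError("dchi_ca must be >= 0")

    def intravascular_dchi(self, so2: Optional[float] = None) -> float:
        """Susceptibility offset of blood vs. tissue in ppm."""
        s = self.so2 if so2 is None else so2
        return self.dchi_deoxy * self.hct * (1.0 - s / 100.0) + self.dchi_ca


@dataclass
class FieldMap:
    """Angular-frequency offset map (rad/s) at field strength ``b0``."""

    grid: GridSpec
    db: np.ndarray
    b0: float
    b0_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.db = np.asarray(self.db, dtype=np.float64)
        if self.db.shape != self.grid.shape:
            raise ValueError("db shape does not match grid")
        if not np.all(np.isfinite(self.db)):
            raise ValueError("field map contains non-finite values")
        ax = np.asarray(self.b0_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("b0_axis must be a non-zero vector")
        self.b0_axis = tuple(ax / n)

    def scaled(self, factor: float) -> "FieldMap":
        """Field for a susceptibility distribution scaled by ``factor``."""
        return FieldMap(self.grid, self.db * factor, self.b0, self.b0_axis,
                        dict(self.meta))


def susceptibility_map(v: VoxelGeometry, s: SusceptibilityState) -> np.ndarray:
    """Per-cell susceptibility offset in ppm (0 outside vessels).

    In the default mode every vessel carries the voxel's single SO2; in the
    distributed mode each labelled vessel uses its own SO2 from
    ``s.per_vessel_so2`` (every present label must be covered).
    """
    chi = np.zeros(v.grid.shape, dtype=np.float64)
    if s.per_vessel_so2 is None:
        chi[v.occupancy] = s.intravascular_dchi()
        return chi
    if v.vessel_labels is None:
        raise ValueError("distributed-SO2 mode requires vessel_labels")
    present = np.unique(v.vessel_labels[v.occupancy])
    missing = [int(l) for l in present if int(l) not in s.per_vessel_so2]
    if missing:
        raise ValueError(f"per_vessel_so2 missing labels {missing}")
    lut = np.zeros(int(present.max()) + 1, dtype=np.float64)
    for lab in present:
        lut[int(lab)] = s.intravascular_dchi(s.per_vessel_so2[int(lab)])
    chi[v.occupancy] = lut[v.vessel_labels[v.occupancy]]
    return chi


def _dipole_solve(chi_ppm: np.ndarray, grid: GridSpec, b0: float,
                  kernel: np.ndarray) -> np.ndarray:
    # chi is real: use the real FFT (kernel is passed pre-sliced to the
    # half-spectrum along the last axis)
    chik = sfft.rfftn(np.asarray(chi_ppm, dtype=np.float64))
    db = sfft.irfftn(kernel * chik, s=grid.shape)
    return GAMMA * b0 * 1e-6 * db


def field_offset(chi_ppm: np.ndarray, grid: GridSpec, b0: float = 4.7,
                 b0_axis=(0.0, 0.0, 1.0)) -> FieldMap:
    """3D dipole-kernel field solve (periodic, k=0 term zeroed)."""
    chi_ppm = np.asarray(chi_ppm, dtype=np.float64)
    if chi_ppm.shape != grid.shape:
        raise ValueError("chi shape does not match grid")
    if not np.all(np.isfinite(chi_ppm)):
        raise ValueError("chi contains non-finite values")
    ax = np.asarray(b0_axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    kx, ky, kz = grid.kgrid()
    kz = kz[..., : grid.shape[2] // 2 + 1]
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * ax[0] + ky * ax[1] + kz * ax[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - kb**2 / k2
    kernel = np.where(k2 == 0.0, 0.0, kernel)
    db = _dipole_solve(chi_ppm, grid, b0, kernel)
    return FieldMap(grid, db, b0, tuple(ax), meta={"kernel": "dipole3d"})


def field_offset_2d(chi_ppm: np.ndarray, grid: GridSpec, b0: float = 4.7,
                    b0_angle: float = 0.0) -> FieldMap:
    """2D dipole-kernel field solve for disk voxels.

    The plane models cross-sections of infinite cylinders perpendicular to
    it, with B0 lying in-plane at ``b0_angle`` radians from the x axis; the
    kernel is ``1/2 - kb^2/|k|^2`` with kb the k-component along B0.
    """
    chi_ppm = np.asarray(chi_ppm, dtype=np.float64)
    if chi_ppm.ndim == 2:
        chi_ppm = chi_ppm[:, :, None]
    if not grid.is_2d or chi_ppm.shape != grid.shape:
        raise ValueError("field_offset_2d requires a 2D grid (nz = 1)")
    kx, ky, _ = grid.kgrid()
    k2 = kx**2 + ky**2
    kb = kx * np.cos(b0_angle) + ky * np.sin(b0_angle)
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 0.5 - kb**2 / k2
    kernel = np.where(k2 == 0.0, 0.0, kernel)
    ax3 = (float(np.cos(b0_angle)), float(np.sin(b0_angle)), 0.0)
    db = _dipole_solve(chi_ppm, grid, b0, kernel)
    return FieldMap(grid, db, b0, ax3, meta={"kernel": "dipole2d",
                                             "b0_angle": b0_angle})


def vessel_field(v: VoxelGeometry, s: SusceptibilityState, b0: float = 4.7,
                 b0_axis=(0.0, 0.0, 1.0), b0_angle: float = 0.0) -> FieldMap:
    """Field map of a voxel geometry under a susceptibility state.

    Dispatches to the 2D kernel for disk voxels and the 3D kernel otherwise.
    """
    chi = susceptibility_map(v, s)
    if v.grid.is_2d:
        return field_offset_2d(chi, v.grid, b0=b0, b0_angle=b0_angle)
    return field_offset(chi, v.grid, b0=b0, b0_axis=b0_axis)
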