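"""Simulation grids.

All geometry and field computations live on a cell-centred rectangular grid
with micrometre spacing. 2D voxels (the disk family) are represented with
``nz = 1``. Axis order is (x, y, z); by convention z is the long (slab) axis
and the default B0 axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular cell-centred grid.

    Parameters
    ----------
    shape : tuple of int
        Number of cells (nx, ny, nz). ``nz == 1`` marks a 2D voxel.
    spacing : tuple of float
        Cell size in micrometres along each axis.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("shape and spacing must have length 3")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def is_2d(self) -> bool:
        return self.shape[2] == 1

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Box size in micrometres along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def cell_centers(self, dtype=np.float64) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coordinate arrays (broadcastable, cell-centred, micrometres)."""
        axes = [
            (np.arange(n, dtype=dtype) + 0.5) * s
            for n, s in zip(self.shape, self.spacing)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def kgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Angular spatial-frequency axes (rad/µm), broadcastable, full FFT order."""
        axes = [
            2.0 * np.pi * np.fft.fftfreq(n, d=s)
            for n, s in zip(self.shape, self.spacing)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))
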