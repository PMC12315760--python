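"""NIfTI and CSV interchange helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import VoxelGeometry
from .grid import GridSpec
from .reconstruct import PARAM_NAMES, ParametricMaps

__all__ = [
    "save_geometry_nifti",
    "load_geometry_nifti",
    "save_field_nifti",
    "save_series_nifti",
    "load_series_nifti",
    "save_maps_nifti",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_geometry_nifti(v: VoxelGeometry, path) -> None:
    """Binary occupancy volume; spacing (µm) carried in the header zooms."""
    img = nib.Nifti1Image(v.occupancy.astype(np.uint8), _affine(v.grid.spacing))
    img.header.set_zooms(v.grid.spacing)
    img.header["descrip"] = f"vascmrf occupancy {v.provenance}".encode()[:80]
    nib.save(img, str(path))


def load_geometry_nifti(path) -> VoxelGeometry:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 2:
        data = data[:, :, None]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = GridSpec(data.shape, spacing)
    v = VoxelGeometry(grid, data > 0.5, provenance="loaded")
    return v


def save_field_nifti(db: np.ndarray, spacing, path) -> None:
    """Field offset map in rad/s."""
    img = nib.Nifti1Image(np.asarray(db, dtype=np.float32), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def save_series_nifti(series: np.ndarray, path) -> None:
    """4D fingerprint series: spatial dims then the sample axis."""
    arr = np.asarray(series, dtype=np.float32)
    if arr.ndim == 3:  # (ny, nx, samples) -> add a singleton slice axis
        arr = arr[:, :, None, :]
    nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))


def load_series_nifti(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if arr.ndim == 4 and arr.shape[2] == 1:
        arr = arr[:, :, 0, :]
    return arr


def save_maps_nifti(maps: ParametricMaps, outdir) -> dict:
    """One NIfTI per parameter plus the quality sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in PARAM_NAMES:
        p = outdir / f"{maps.method}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(maps.maps[name].astype(np.float32),
                                 np.eye(4)), str(p))
        paths[name] = p
    if maps.quality is not None:
        p = outdir / f"{maps.method}_quality.nii.gz"
        nib.save(nib.Nifti1Image(maps.quality.astype(np.float32),
                                 np.eye(4)), str(p))
        paths["quality"] = p
    return paths
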