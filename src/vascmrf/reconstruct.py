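"""Parameter estimation from fingerprints: matching (DBM) and learning (DBL).

DBM scores an acquired fingerprint against every dictionary entry by dot
product and returns the best-matching entry's parameters (estimates
therefore live on the dictionary grid). DBL trains a GLLiM inverse
regression on the dictionary and returns posterior means, which can fall
between simulated parameter values — and also outside physical ranges,
hence the clipping rules: BVf and SO2 are clipped to [0, 100] %, R to
[0, 250] µm, and T2 only to 0 ms on the lower end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .dictionary import FingerprintDictionary
from .gesfidse import Fingerprint
from .gllim import GLLiM

__all__ = [
    "PARAM_NAMES",
    "CLIP_BOUNDS",
    "EstimateVector",
    "ParametricMaps",
    "clip_estimates",
    "clip_parameter_table",
    "dbm_match",
    "dbm_match_batch",
    "dbl_train",
    "dbl_predict",
    "dbl_predict_batch",
    "reconstruct_maps",
]

PARAM_NAMES = ("bvf", "radius", "so2", "t2")

#: physical clipping bounds (lower, upper); None = unbounded
CLIP_BOUNDS = {
    "bvf": (0.0, 100.0),
    "so2": (0.0, 100.0),
    "radius": (0.0, 250.0),
    "t2": (0.0, None),
}


@dataclass
class EstimateVector:
    """One voxel's estimated parameters with clipping flags and quality."""

    bvf: float
    radius: float
    so2: float
    t2: float
    clipped_flags: dict = field(default_factory=dict)
    match_score: Optional[float] = None
    posterior_sd: Optional[dict] = None

    def as_array(self) -> np.ndarray:
        return np.array([self.bvf, self.radius, self.so2, self.t2])


@dataclass
class ParametricMaps:
    """Spatial maps of the four parameters plus a quality sidecar.

    Masked-out voxels hold NaN (never 0, which is a legal parameter value).
    """

    maps: dict
    mask: np.ndarray
    method: str
    quality: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) != 1 or self.mask.shape not in shapes:
            raise ValueError("all maps and the mask must share one shape")


def clip_parameter_table(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip an (n, 4) array in canonical order; returns (clipped, flags)."""
    v = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("estimates must be finite before clipping")
    out = v.copy()
    flags = np.zeros(v.shape, dtype=bool)
    for j, name in enumerate(PARAM_NAMES):
        lo, hi = CLIP_BOUNDS[name]
        col = out[..., j]
        low = col < lo
        col[low] = lo
        flags[..., j] |= low
        if hi is not None:
            high = col > hi
            col[high] = hi
            flags[..., j] |= high
    return out, flags


def clip_estimates(e: EstimateVector) -> EstimateVector:
    """Apply the physical-range clipping rules; idempotent."""
    clipped, flags = clip_parameter_table(e.as_array()[None, :])
    return EstimateVector(
        bvf=clipped[0, 0], radius=clipped[0, 1], so2=clipped[0, 2],
        t2=clipped[0, 3],
        clipped_flags={n: bool(f) for n, f in zip(PARAM_NAMES, flags[0])},
        match_score=e.match_score, posterior_sd=e.posterior_sd,
    )


def _as_signal(fp: Union[Fingerprint, np.ndarray]) -> np.ndarray:
    x = fp.values if isinstance(fp, Fingerprint) else np.asarray(fp, float)
    n = np.linalg.norm(x)
    if n == 0 or not np.all(np.isfinite(x)):
        raise ValueError("fingerprint must be finite and non-zero")
    return x / n


def dbm_match_batch(signals: np.ndarray, d: FingerprintDictionary,
                    chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Indices and dot-product scores of the best dictionary match per row.

    Ties resolve to the lowest row index (argmax convention).
    """
    X = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    if X.shape[1] != d.signal_length:
        raise ValueError(
            f"fingerprint length {X.shape[1]} does not match dictionary "
            f"signal length {d.signal_length}"
        )
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero fingerprints cannot be matched")
    X = X / norms
    idx = np.empty(len(X), dtype=np.int64)
    score = np.empty(len(X))
    for i0 in range(0, len(X), chunk):
        s = X[i0:i0 + chunk] @ d.signals.T
        idx[i0:i0 + chunk] = s.argmax(axis=1)
        score[i0:i0 + chunk] = s.max(axis=1)
    return idx, score


def dbm_match(fp: Union[Fingerprint, np.ndarray],
              d: FingerprintDictionary) -> EstimateVector:
    """Best dictionary entry for one fingerprint (highest dot product)."""
    x = _as_signal(fp)
    idx, score = dbm_match_batch(x[None, :], d)
    row = d.params.iloc[int(idx[0])]
    return EstimateVector(bvf=float(row["bvf"]), radius=float(row["radius"]),
                          so2=float(row["so2"]), t2=float(row["t2"]),
                          clipped_flags={n: False for n in PARAM_NAMES},
                          match_score=float(score[0]))


def dbl_train(d: FingerprintDictionary, n_components: int = 50,
              seed: int = 0, **kwargs) -> GLLiM:
    """Train the GLLiM inverse regression on a dictionary."""
    model = GLLiM(n_components=n_components, seed=seed, **kwargs)
    model.fit(d.parameter_array(), d.signals)
    model.training_meta["param_names"] = list(PARAM_NAMES)
    model.training_meta["dictionary_meta"] = d.meta
    return model


def dbl_predict_batch(model: GLLiM, signals: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clipped posterior means, clip flags and posterior sd for (n, D) input."""
    X = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero fingerprints cannot be predicted")
    mean, sd = model.predict(X / norms)
    clipped, flags = clip_parameter_table(mean)
    return clipped, flags, sd


def dbl_predict(model: GLLiM, fp: Union[Fingerprint, np.ndarray]
                ) -> EstimateVector:
    """Posterior-mean estimate for one fingerprint, clipped to physics."""
    x = _as_signal(fp)
    clipped, flags, sd = dbl_predict_batch(model, x[None, :])
    return EstimateVector(
        bvf=clipped[0, 0], radius=clipped[0, 1], so2=clipped[0, 2],
        t2=clipped[0, 3],
        clipped_flags={n: bool(f) for n, f in zip(PARAM_NAMES, flags[0])},
        posterior_sd=dict(zip(PARAM_NAMES, sd[0])),
    )


def reconstruct_maps(series: np.ndarray,
                     model_or_dict: Union[GLLiM, FingerprintDictionary],
                     method: str,
                     mask: Optional[np.ndarray] = None) -> ParametricMaps:
    """Voxelwise reconstruction of a fingerprint image series.

    ``series`` has the fingerprint along the last axis; any spatial shape is
    accepted. ``method`` is ``"dbm"`` (requires a dictionary) or ``"dbl"``
    (requires a trained model).
    """
    series = np.asarray(series, dtype=np.float64)
    spatial = series.shape[:-1]
    flat = series.reshape(-1, series.shape[-1])
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise ValueError("mask shape does not match the series")
    sel = mask.reshape(-1)

    maps = {n: np.full(spatial, np.nan) for n in PARAM_NAMES}
    quality = np.full(spatial, np.nan)
    if method == "dbm":
        if not isinstance(model_or_dict, FingerprintDictionary):
            raise TypeError("DBM reconstruction requires a FingerprintDictionary")
        idx, score = dbm_match_batch(flat[sel], model_or_dict)
        table = model_or_dict.parameter_array()[idx]
        qual = score
        meta = {"dictionary_meta": model_or_dict.meta}
    elif method == "dbl":
        if not isinstance(model_or_dict, GLLiM):
            raise TypeError("DBL reconstruction requires a trained GLLiM model")
        table, _flags, sd = dbl_predict_batch(model_or_dict, flat[sel])
        qual = sd.mean(axis=1)
        meta = {"training_meta": model_or_dict.training_meta}
    else:
        raise ValueError(f"unknown method {method!r}; use 'dbm' or 'dbl'")

    for j, name in enumerate(PARAM_NAMES):
        m = maps[name].reshape(-1)
        m[sel] = table[:, j]
    q = quality.reshape(-1)
    q[sel] = qual
    return ParametricMaps(maps=maps, mask=mask, method=method,
                          quality=quality, meta=meta)
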