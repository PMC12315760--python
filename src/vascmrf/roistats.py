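"""ROI averaging and group comparison.

Parameter values are averaged inside each region of interest for each unit
(animal or phantom); those per-unit means are the samples of a two-sided
two-sample t-test (Student by default, Welch optionally). Pooling voxels
across units is deliberately not the default: it inflates significance by
treating correlated voxels as independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .reconstruct import ParametricMaps

__all__ = ["ROIStats", "roi_mean", "compare_groups", "roi_compare"]

ALPHA = 0.05


@dataclass(frozen=True)
class ROIStats:
    """Result of one two-sample comparison on per-unit ROI means."""

    parameter: str
    mean_a: float
    mean_b: float
    effect: float  # mean_a - mean_b
    t: float
    p: float
    significant: bool
    variant: str  # "student" | "welch"
    n_a: int
    n_b: int


def roi_mean(maps: ParametricMaps, roi: np.ndarray) -> dict:
    """Mean of each parameter map inside a boolean ROI (NaN-aware)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    out = {}
    for name, m in maps.maps.items():
        vals = m[roi]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"ROI contains no reconstructed voxels for {name}")
        out[name] = float(vals.mean())
    return out


def compare_groups(means_a: Sequence[float], means_b: Sequence[float],
                   parameter: str = "", welch: bool = False) -> ROIStats:
    """Two-sided two-sample t-test on per-unit ROI means."""
    a = np.asarray(list(means_a), dtype=float)
    b = np.asarray(list(means_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 units")
    if np.array_equal(a, b):
        # degenerate identical groups: no evidence of a difference
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return ROIStats(parameter=parameter, mean_a=float(a.mean()),
                    mean_b=float(b.mean()), effect=float(a.mean() - b.mean()),
                    t=t, p=p, significant=bool(p <= ALPHA),
                    variant="welch" if welch else "student",
                    n_a=len(a), n_b=len(b))


def roi_compare(maps_a: Sequence[ParametricMaps],
                maps_b: Sequence[ParametricMaps],
                roi_a: np.ndarray, roi_b: np.ndarray,
                parameter: str, welch: bool = False) -> ROIStats:
    """Compare a parameter between two groups of units.

    Each element of ``maps_a``/``maps_b`` is one unit; its ROI mean is
    computed first and the t-test runs on those means.
    """
    a = [roi_mean(m, roi_a)[parameter] for m in maps_a]
    b = [roi_mean(m, roi_b)[parameter] for m in maps_b]
    return compare_groups(a, b, parameter=parameter, welch=welch)
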