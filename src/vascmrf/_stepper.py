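"""Low-level periodic separable convolution kernels (numba-compiled).

The diffusion operator applied at each Bloch step is a separable periodic
blur; these per-axis passes are the hot loop of dictionary generation. The
axis-0/1 passes accumulate whole contiguous slabs (the wrap index is hoisted
out of the inner loops so they vectorize); axis 2 has a branch-free interior
with a specialized 3-tap path, which is the common case for the
variance-exact diffusion stencil.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _conv_axis0(m, taps, out):
    nx, ny, nz = m.shape
    K = taps.shape[0] // 2
    for i in range(nx):
        for t in range(-K, K + 1):
            ii = (i + t) % nx
            w = taps[t + K]
            if t == -K:
                for j in range(ny):
                    for k in range(nz):
                        out[i, j, k] = w * m[ii, j, k]
            else:
                for j in range(ny):
                    for k in range(nz):
                        out[i, j, k] += w * m[ii, j, k]


@njit(cache=True, fastmath=True)
def _conv_axis1(m, taps, out):
    nx, ny, nz = m.shape
    K = taps.shape[0] // 2
    for j in range(ny):
        for t in range(-K, K + 1):
            jj = (j + t) % ny
            w = taps[t + K]
            if t == -K:
                for i in range(nx):
                    for k in range(nz):
                        out[i, j, k] = w * m[i, jj, k]
            else:
                for i in range(nx):
                    for k in range(nz):
                        out[i, j, k] += w * m[i, jj, k]


@njit(cache=True, fastmath=True)
def _conv_axis2_k1(m, w0, w1, out):
    nx, ny, nz = m.shape
    for i in range(nx):
        for j in range(ny):
            out[i, j, 0] = w0 * m[i, j, 0] + w1 * (m[i, j, 1] + m[i, j, nz - 1])
            for k in range(1, nz - 1):
                out[i, j, k] = (w0 * m[i, j, k]
                                + w1 * (m[i, j, k + 1] + m[i, j, k - 1]))
            out[i, j, nz - 1] = (w0 * m[i, j, nz - 1]
                                 + w1 * (m[i, j, 0] + m[i, j, nz - 2]))


@njit(cache=True, fastmath=True)
def _conv_axis2(m, taps, out):
    nx, ny, nz = m.shape
    K = taps.shape[0] // 2
    for i in range(nx):
        for j in range(ny):
            for k in range(K, nz - K):
                acc = taps[K] * m[i, j, k]
                for t in range(1, K + 1):
                    acc += taps[K + t] * (m[i, j, k + t] + m[i, j, k - t])
                out[i, j, k] = acc
            for k in range(K):
                acc = taps[K] * m[i, j, k]
                for t in range(1, K + 1):
                    acc += taps[K + t] * (m[i, j, (k + t) % nz]
                                          + m[i, j, (k - t) % nz])
                out[i, j, k] = acc
            for k in range(nz - K, nz):
                acc = taps[K] * m[i, j, k]
                for t in range(1, K + 1):
                    acc += taps[K + t] * (m[i, j, (k + t) % nz]
                                          + m[i, j, (k - t) % nz])
                out[i, j, k] = acc


def _conv_numba(m, taps, axis, out):
    if axis == 0:
        _conv_axis0(m, taps, out)
    elif axis == 1:
        _conv_axis1(m, taps, out)
    elif len(taps) == 3:
        _conv_axis2_k1(m, taps[1], taps[2], out)
    else:
        _conv_axis2(m, taps, out)


def _conv_numpy(m, taps, axis, out):
    K = len(taps) // 2
    acc = taps[K] * m
    for t in range(1, K + 1):
        acc = acc + taps[K + t] * (np.roll(m, t, axis=axis)
                                   + np.roll(m, -t, axis=axis))
    out[...] = acc


def diffuse(m: np.ndarray, taps_per_axis, scratch: np.ndarray) -> np.ndarray:
    """Apply the separable periodic blur; returns the blurred array.

    ``taps_per_axis`` is a sequence of symmetric tap vectors (or None to
    skip an axis). ``m`` and ``scratch`` are swapped internally; the caller
    must use both the return value and ``m``/``scratch`` as opaque buffers.
    """
    if m.ndim != 3:
        raise ValueError("diffuse expects 3D arrays")
    cur, other = m, scratch
    for axis, taps in enumerate(taps_per_axis):
        if taps is None or len(taps) == 1:
            continue
        if _HAVE_NUMBA:
            _conv_numba(cur, taps, axis, other)
        else:
            _conv_numpy(cur, taps, axis, other)
        cur, other = other, cur
    return cur
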