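"""Minimal orthonormal 2-D Haar wavelet transform.

Backs the DWT fusion baseline only.  Kept deliberately small: one
separable orthonormal filter pair, multi-level on the approximation,
exact reconstruction.  Odd extents are handled by edge-replicating one
row/column before a level and cropping after its inverse.
"""

from __future__ import annotations

import numpy as np

_SQRT2 = np.sqrt(2.0)

#: One decomposition level: (approx, (detail_h, detail_v, detail_d), original_shape)
Level = tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray], tuple[int, int]]


def _haar_1d(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.take(x, range(0, x.shape[axis], 2), axis=axis)
    b = np.take(x, range(1, x.shape[axis], 2), axis=axis)
    return (a + b) / _SQRT2, (a - b) / _SQRT2


def _ihaar_1d(lo: np.ndarray, hi: np.ndarray, axis: int) -> np.ndarray:
    a = (lo + hi) / _SQRT2
    b = (lo - hi) / _SQRT2
    shape = list(lo.shape)
    shape[axis] *= 2
    out = np.empty(shape, dtype=float)
    sl_a = [slice(None)] * lo.ndim
    sl_b = [slice(None)] * lo.ndim
    sl_a[axis] = slice(0, None, 2)
    sl_b[axis] = slice(1, None, 2)
    out[tuple(sl_a)] = a
    out[tuple(sl_b)] = b
    return out


def _pad_even(x: np.ndarray) -> np.ndarray:
    pr = x.shape[0] % 2
    pc = x.shape[1] % 2
    if pr or pc:
        x = np.pad(x, ((0, pr), (0, pc)), mode="edge")
    return x


def haar_decompose(x: np.ndarray, levels: int = 2) -> tuple[np.ndarray, list[Level]]:
    """Multi-level 2-D Haar DWT; returns (final approx, per-level details)."""
    x = np.asarray(x, dtype=float)
    detail: list[Level] = []
    approx = x
    for _ in range(levels):
        shape = approx.shape
        a = _pad_even(approx)
        lo_r, hi_r = _haar_1d(a, axis=0)
        ll, lh = _haar_1d(lo_r, axis=1)
        hl, hh = _haar_1d(hi_r, axis=1)
        detail.append((ll, (lh, hl, hh), shape))
        approx = ll
    return approx, detail


def haar_reconstruct(approx: np.ndarray, detail: list[Level]) -> np.ndarray:
    """Exact inverse of :func:`haar_decompose`."""
    x = approx
    for _, (lh, hl, hh), shape in reversed(detail):
        lo_r = _ihaar_1d(x, lh, axis=1)
        hi_r = _ihaar_1d(hl, hh, axis=1)
        x = _ihaar_1d(lo_r, hi_r, axis=0)
        x = x[: shape[0], : shape[1]]
    return x
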