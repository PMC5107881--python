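"""Fused inner-loop kernel for the fold-batched trainer.

Non-overlapping width-2 max pooling over the convolution axis is
memory-bound and dominated by strided reads when written as numpy
expressions; the fused loop below roughly halves the epoch cost.
Compiled lazily with numba (disk cache on), with an equivalent numpy
fallback if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(f):
            return f
        return deco


@njit(cache=True)
def _pool2_jit(y: np.ndarray, P: int):
    F, S, L, K = y.shape
    pooled = np.empty((F, S, P, K), np.float32)
    mask = np.empty((F, S, P, K), np.bool_)
    for f in range(F):
        for s in range(S):
            for p in range(P):
                for k in range(K):
                    a = y[f, s, 2 * p, k]
                    b = y[f, s, 2 * p + 1, k]
                    m = b > a
                    mask[f, s, p, k] = m
                    pooled[f, s, p, k] = b if m else a
    return pooled, mask


def pool2(y: np.ndarray, P: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping width-2 max pool over axis 2 of (F, S, L, K).

    Returns (pooled, mask) where mask marks blocks won by the odd (second)
    position; ties go to the even (first) position.
    """
    if _HAVE_NUMBA:
        return _pool2_jit(y, P)
    even = y[:, :, 0:2 * P:2]
    odd = y[:, :, 1:2 * P:2]
    mask = odd > even
    return np.maximum(even, odd), mask
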