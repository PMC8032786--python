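"""Needleman-Wunsch global-alignment score kernel.

Two-row dynamic program maximizing the total substitution + gap score.
The hot loop is numba-jitted when numba is importable; a pure-Python
fallback keeps the package functional without it.
"""
from __future__ import annotations

import numpy as np

__all__ = ["nw_score"]


def _nw_score_py(a, b, sub, gap):
    n, m = len(a), len(b)
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[0] = 0.0
    for j in range(1, m + 1):
        prev[j] = prev[j - 1] + gap
    for i in range(1, n + 1):
        cur[0] = prev[0] + gap
        ai = a[i - 1]
        for j in range(1, m + 1):
            best = prev[j - 1] + sub[ai, b[j - 1]]
            up = prev[j] + gap
            if up > best:
                best = up
            left = cur[j - 1] + gap
            if left > best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _nw_score_jit = njit(cache=True, fastmath=False)(_nw_score_py)

    def nw_score(a: np.ndarray, b: np.ndarray, sub: np.ndarray, gap: float) -> float:
        return float(_nw_score_jit(a, b, sub, gap))

except ImportError:  # pragma: no cover

    def nw_score(a: np.ndarray, b: np.ndarray, sub: np.ndarray, gap: float) -> float:
        return float(_nw_score_py(a, b, sub, gap))
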