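"""Minimal empirical mode decomposition: extraction of the first IMF.

Standard sifting with cubic-spline envelopes through local extrema and a
Cauchy-type stopping criterion on the normalized squared change between
successive sifts.  Endpoints are treated as extrema of both envelopes,
which avoids end-swing without mirroring.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    return maxima, minima


def first_imf(x: np.ndarray, sd_threshold: float = 0.3, max_sifts: int = 100) -> np.ndarray:
    """Return the first intrinsic mode function of ``x``.

    If the signal has too few interior extrema to build envelopes it is its
    own residual and is returned mean-centred.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 7:
        return x - x.mean()
    idx = np.arange(n)
    h = x.copy()
    for _ in range(max_sifts):
        maxima, minima = _extrema(h)
        if maxima.size < 2 or minima.size < 2:
            break
        up_idx = np.concatenate(([0], maxima, [n - 1]))
        lo_idx = np.concatenate(([0], minima, [n - 1]))
        upper = CubicSpline(up_idx, h[up_idx])(idx)
        lower = CubicSpline(lo_idx, h[lo_idx])(idx)
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        denom = float(np.sum(h * h)) + 1e-12
        sd = float(np.sum(mean_env * mean_env)) / denom
        h = h_new
        if sd < sd_threshold:
            break
    return h
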