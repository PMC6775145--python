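"""Numba-compiled inner loops for the feature extractor.

Everything here is a pure function of its arguments; the public API lives
in :mod:`hrvstage.features`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def template_match_counts(x: np.ndarray, max_m: int, r: float) -> tuple:
    """Pair counts for sample entropy.

    Returns ``(full, restricted)`` where ``full[k-1]`` counts pairs (i, j),
    i < j, whose templates of length k match under the Chebyshev distance
    with tolerance r (self-matches excluded), and ``restricted[k-1]`` counts
    the subset of those pairs for which a (k+1)-length extension exists
    (i.e. j + k < n).  Per the standard definition,
    SampEn(m, r) = -ln(full[m] / restricted[m-1]).
    """
    n = x.size
    full = np.zeros(max_m, dtype=np.int64)
    restricted = np.zeros(max_m, dtype=np.int64)
    for i in range(n - 1):
        for j in range(i + 1, n):
            k = 0
            while k < max_m and j + k < n:
                if abs(x[i + k] - x[j + k]) > r:
                    break
                k += 1
                full[k - 1] += 1
            # lengths with room for one more element (j is the binding index)
            kr = min(k, n - 1 - j)
            for m in range(kr):
                restricted[m] += 1
    return full, restricted


@njit(cache=True)
def nvg_adjacency(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Natural-visibility-graph adjacency matrix.

    Nodes a < b are connected iff every intermediate sample lies strictly
    below the straight line joining them; equivalently iff the slope from a
    to b strictly exceeds the running maximum slope from a to any
    intermediate point.
    """
    n = t.size
    adj = np.zeros((n, n), dtype=np.uint8)
    for a in range(n - 1):
        max_slope = -1.0e308
        for b in range(a + 1, n):
            s = (y[b] - y[a]) / (t[b] - t[a])
            if s > max_slope:
                adj[a, b] = 1
                adj[b, a] = 1
                max_slope = s
    return adj


@njit(cache=True)
def dfa_fluctuations(rr: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """RMS detrended fluctuation F(n) of the integrated mean-centred series.

    Non-overlapping boxes are taken from both ends of the series (the
    standard symmetrization when the length is not a multiple of n, which
    also makes F exactly invariant under time reversal); a linear trend is
    removed from each box; F(n) = sqrt(mean squared residual).
    """
    n_samples = rr.size
    # profile with a leading zero: under time reversal the profile maps to
    # its own negated mirror image, so both-ends boxing is exactly invariant
    n_prof = n_samples + 1
    y = np.empty(n_prof)
    mu = rr.mean()
    acc = 0.0
    y[0] = 0.0
    for i in range(n_samples):
        acc += rr[i] - mu
        y[i + 1] = acc
    out = np.full(scales.size, np.nan)
    for si in range(scales.size):
        n = scales[si]
        n_boxes = n_prof // n
        if n_boxes < 1:
            continue
        # closed-form linear detrend per box using index moments
        sx = 0.0
        sxx = 0.0
        for k in range(n):
            sx += k
            sxx += k * k
        denom = n * sxx - sx * sx
        total = 0.0
        offsets = (0, n_prof - n_boxes * n)
        for off in offsets:
            for b in range(n_boxes):
                sy = 0.0
                sxy = 0.0
                for k in range(n):
                    v = y[off + b * n + k]
                    sy += v
                    sxy += k * v
                slope = (n * sxy - sx * sy) / denom
                intercept = (sy - slope * sx) / n
                for k in range(n):
                    resid = y[off + b * n + k] - (intercept + slope * k)
                    total += resid * resid
            if offsets[1] == 0:
                total *= 2.0  # exact multiple: both passes identical
                break
        out[si] = np.sqrt(total / (2 * n_boxes * n))
    return out


@njit(cache=True)
def coordination_masks(sgn: np.ndarray) -> tuple:
    """Masks of sign positions inside back-to-back repeated patterns.

    For pattern lengths p = 3..8, a maximal run of r >= 2 identical
    consecutive blocks marks the positions of the repeated blocks (the
    (r-1)*p positions after the first block instance): exactly-2-repetition
    runs go to the first mask, >=3 to the second.
    """
    L = sgn.size
    cov2 = np.zeros(L, dtype=np.uint8)
    cov3 = np.zeros(L, dtype=np.uint8)
    for p in range(3, 9):
        if L < 2 * p:
            continue
        beq = np.zeros(L, dtype=np.uint8)
        for i in range(L - 2 * p + 1):
            ok = True
            for k in range(p):
                if sgn[i + k] != sgn[i + p + k]:
                    ok = False
                    break
            if ok:
                beq[i] = 1
        cnt = np.zeros(L, dtype=np.int64)
        for i in range(L - 2 * p, -1, -1):
            if beq[i]:
                cnt[i] = 1 + (cnt[i + p] if i + p <= L - 2 * p else 0)
        for i in range(L - 2 * p + 1):
            if beq[i] and (i < p or not beq[i - p]):
                r = cnt[i] + 1  # repetitions of the block
                end = i + r * p
                if r == 2:
                    for k in range(i + p, end):
                        cov2[k] = 1
                elif r >= 3:
                    for k in range(i + p, end):
                        cov3[k] = 1
    return cov2, cov3


@njit(cache=True)
def sync_masks(sgn: np.ndarray) -> np.ndarray:
    """Per-ratio masks of n:2 phase-synchronized sign positions.

    Row k corresponds to n = 6 + k.  A window of n consecutive signs
    matching any circular shift of ceil(n/2) '+' followed by floor(n/2) '-'
    marks all n positions.
    """
    L = sgn.size
    masks = np.zeros((4, L), dtype=np.uint8)
    for row in range(4):
        n = 6 + row
        if L < n:
            continue
        n_plus = (n + 1) // 2
        template = np.zeros(n, dtype=np.int8)
        for k in range(n_plus):
            template[k] = 1
        for i in range(L - n + 1):
            matched = False
            for shift in range(n):
                ok = True
                for k in range(n):
                    if sgn[i + k] != template[(k + shift) % n]:
                        ok = False
                        break
                if ok:
                    matched = True
                    break
            if matched:
                for k in range(n):
                    masks[row, i + k] = 1
    return masks


@njit(cache=True)
def higuchi_lengths(x: np.ndarray, k_max: int) -> np.ndarray:
    """Mean normalized curve length L(k) for k = 1..k_max."""
    n = x.size
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        total = 0.0
        n_series = 0
        for m in range(k):
            n_points = (n - 1 - m) // k
            if n_points < 1:
                continue
            length = 0.0
            for i in range(1, n_points + 1):
                length += abs(x[m + i * k] - x[m + (i - 1) * k])
            length *= (n - 1) / (n_points * k * k)
            total += length
            n_series += 1
        out[k - 1] = total / n_series if n_series else np.nan
    return out


@njit(cache=True)
def ipfm_beats(rate_grid_t: np.ndarray, rr_s: np.ndarray, t0: float) -> np.ndarray:
    """Integral pulse frequency modulation beat times.

    ``rr_s`` is the instantaneous RR (seconds) sampled on the uniform grid
    ``rate_grid_t``; a beat fires whenever the integral of 1/RR(t) crosses
    the next integer.  Linear interpolation within grid steps.
    """
    n = rate_grid_t.size
    max_beats = int((rate_grid_t[-1] - rate_grid_t[0]) / rr_s.min()) + 2
    beats = np.empty(max_beats, dtype=np.float64)
    nb = 0
    phase = 0.0
    target = 1.0
    for i in range(n - 1):
        dt = rate_grid_t[i + 1] - rate_grid_t[i]
        rate = 0.5 * (1.0 / rr_s[i] + 1.0 / rr_s[i + 1])
        new_phase = phase + rate * dt
        while new_phase >= target:
            frac = (target - phase) / (new_phase - phase)
            beats[nb] = rate_grid_t[i] + frac * dt
            nb += 1
            target += 1.0
        phase = new_phase
    return beats[:nb] + t0
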