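"""The 132-feature HRV battery, computed per 30-s epoch.

Each epoch is described by features from 15 families (time-domain
statistics, detrended fluctuation analysis, spectral measures, multiscale
sample entropy, symbolic dynamics, cardiorespiratory phase coordination and
synchronization, Higuchi fractal dimension, Teager-energy morphology on the
IBI series and its first intrinsic mode function, a heart-rate-surge
arousal-probability surrogate, and natural/difference visibility graphs).

Windows are centred on the epoch: 270 s by default, 510 s for multiscale
entropy, 330 s for windowed DFA.  At recording edges a truncated window is
used if at least half the nominal length remains, otherwise the family is
missing for that epoch.  Missing values are NaN; imputation is the model's
job, never the extractor's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from . import _kernels
from .emd import first_imf
from .io import EpochGrid, IBISeries
from .registry import (MSE_SCALES, N_FEATURES, PERCENTILES, SYNC_RATIOS,
                       family_slice, feature_names)

LN_FLOOR = 1e-10  # ms^2 floor inside logarithms of band powers


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window lengths (seconds) and the usability thresholds."""

    default_len_s: float = 270.0
    mse_len_s: float = 510.0
    wdfa_len_s: float = 330.0
    min_valid_fraction: float = 0.8
    min_coverage_fraction: float = 0.5  # truncated window must keep this much

    def __post_init__(self) -> None:
        for L in (self.default_len_s, self.mse_len_s, self.wdfa_len_s):
            if (L / 30.0) % 2 != 1:
                raise ValueError("window lengths must be odd multiples of 30 s")


@dataclass
class FeatureTable:
    """n_epochs x 132 feature values (NaN = missing) in registry order."""

    values: np.ndarray
    valid_beat_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature table must have {N_FEATURES} columns")

    @property
    def n_epochs(self) -> int:
        return int(self.values.shape[0])

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def names(self) -> tuple[str, ...]:
        return feature_names()


# ---------------------------------------------------------------------------
# Windowing


def window_slice(series: IBISeries, grid: EpochGrid, epoch: int,
                 window_len_s: float) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Valid beats inside the window centred on ``epoch``.

    Returns ``(times, rr, n_total, n_valid)`` where n_total counts all beats
    (valid or not) in the window.  The window is ``[c - L/2, c + L/2)`` with
    c the epoch centre, truncated at the recording edges without padding.
    """
    if not 0 <= epoch < grid.n_epochs:
        raise IndexError(f"epoch {epoch} outside grid of {grid.n_epochs}")
    c = grid.center_of(epoch)
    lo = max(0.0, c - window_len_s / 2.0)
    hi = min(series.duration_s, c + window_len_s / 2.0)
    i0, i1 = np.searchsorted(series.beat_times_s, [lo, hi], side="left")
    mask = series.valid[i0:i1]
    return (series.beat_times_s[i0:i1][mask], series.rr_ms[i0:i1][mask],
            int(i1 - i0), int(mask.sum()))


def _window_coverage(duration_s: float, center: float, window_len_s: float) -> float:
    lo = max(0.0, center - window_len_s / 2.0)
    hi = min(duration_s, center + window_len_s / 2.0)
    return max(0.0, hi - lo) / window_len_s


# ---------------------------------------------------------------------------
# Time-domain families


def detrend_rr(rr: np.ndarray) -> np.ndarray:
    """Remove the OLS line of RR versus beat index; NaN-free input required."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        return np.full(rr.size, np.nan)
    x = np.arange(rr.size, dtype=float)
    slope, intercept = np.polyfit(x, rr, 1)
    return rr - (intercept + slope * x)


def basic_and_variability_features(rr: np.ndarray) -> np.ndarray:
    """4 basic + 12 variability statistics (order: see registry)."""
    out = np.full(16, np.nan)
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        return out
    hr = 60000.0 / rr
    out[0] = rr.mean()
    out[1] = np.median(rr)
    out[2] = hr.mean()
    out[3] = np.median(hr)
    det = detrend_rr(rr)
    for k, sig in enumerate((rr, det)):
        if np.any(np.isnan(sig)):
            continue
        d = np.diff(sig)
        out[4 + k] = sig.std(ddof=1)                       # sdnn
        out[6 + k] = sig.max() - sig.min()                 # range
        out[8 + k] = 100.0 * np.mean(np.abs(d) > 50.0)     # pnn50
        out[10 + k] = math.sqrt(np.mean(d * d))            # rmssd
        out[12 + k] = d.std(ddof=1) if d.size >= 2 else np.nan  # sdsd
        out[14 + k] = np.mean(np.abs(sig - sig.mean()))    # mad
    return out


def percentile_features(rr: np.ndarray) -> np.ndarray:
    """7 percentiles x {RR, HR} x {absolute, detrended} (28 values)."""
    out = np.full(28, np.nan)
    rr = np.asarray(rr, dtype=float)
    if rr.size < 20:
        return out
    hr = 60000.0 / rr
    q = list(PERCENTILES)
    out[0:7] = np.percentile(rr, q)
    out[7:14] = np.percentile(detrend_rr(rr), q)
    out[14:21] = np.percentile(hr, q)
    out[21:28] = np.percentile(detrend_rr(hr), q)
    return out


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis

_SCALES_ALL = np.unique(np.concatenate([
    np.round(np.geomspace(4, 64, 14)).astype(np.int64), [16]]))
_SCALES_PDFA = np.unique(np.concatenate([
    np.round(np.geomspace(4, 16, 7)).astype(np.int64), [16]]))


def _dfa_alpha(rr: np.ndarray, scales: np.ndarray) -> tuple[float, np.ndarray]:
    fluct = _kernels.dfa_fluctuations(np.ascontiguousarray(rr, dtype=float),
                                      scales)
    # small-scale bias correction for linear detrending: for uncorrelated
    # input E[F^2(s)] = sigma^2 (s^2 - 4)/(15 s), so dividing F by
    # sqrt(1 - 4/s^2) restores the s^0.5 law at small box sizes
    fluct = fluct / np.sqrt(1.0 - 4.0 / scales.astype(float) ** 2)
    ok = np.isfinite(fluct) & (fluct > 0)
    if ok.sum() < 3:
        return np.nan, fluct
    slope = np.polyfit(np.log(scales[ok].astype(float)), np.log(fluct[ok]), 1)[0]
    return float(slope), fluct


def dfa_features(rr270: np.ndarray, series: IBISeries, grid: EpochGrid,
                 epoch: int, spec: WindowSpec) -> np.ndarray:
    """alpha_all, alpha_short, alpha_long, F(16), WDFA, PDFA (6 values)."""
    out = np.full(6, np.nan)
    rr270 = np.asarray(rr270, dtype=float)
    if rr270.size < 100:
        return out
    alpha_all, fluct = _dfa_alpha(rr270, _SCALES_ALL)
    out[0] = alpha_all
    short = _SCALES_ALL[_SCALES_ALL <= 16]
    out[1] = _dfa_alpha(rr270, short)[0]
    long_ = _SCALES_ALL[_SCALES_ALL >= 16]
    out[2] = _dfa_alpha(rr270, long_)[0]
    idx16 = int(np.flatnonzero(_SCALES_ALL == 16)[0])
    f16 = fluct[idx16]
    out[3] = f16 if np.isfinite(f16) and f16 > 0 else np.nan

    # WDFA: mean alpha_all over 270-s sub-windows stepped 30 s through the
    # 330-s window.
    c = grid.center_of(epoch)
    alphas = []
    for shift in (-30.0, 0.0, 30.0):
        lo = c + shift - spec.default_len_s / 2.0
        hi = c + shift + spec.default_len_s / 2.0
        lo = max(0.0, lo)
        hi = min(series.duration_s, hi)
        i0, i1 = np.searchsorted(series.beat_times_s, [lo, hi], side="left")
        m = series.valid[i0:i1]
        sub = series.rr_ms[i0:i1][m]
        if sub.size >= 100:
            a = _dfa_alpha(sub, _SCALES_ALL)[0]
            if np.isfinite(a):
                alphas.append(a)
    out[4] = float(np.mean(alphas)) if alphas else np.nan

    # PDFA: mean per-segment alpha over consecutive 64-beat segments.
    n_seg = rr270.size // 64
    seg_alphas = []
    for s in range(n_seg):
        a = _dfa_alpha(rr270[s * 64:(s + 1) * 64], _SCALES_PDFA)[0]
        if np.isfinite(a):
            seg_alphas.append(a)
    out[5] = float(np.mean(seg_alphas)) if seg_alphas else np.nan
    return out


# ---------------------------------------------------------------------------
# Spectral families

HF_BAND = (0.15, 0.40)
LF_BAND = (0.04, 0.15)
VLF_BAND = (0.003, 0.04)
FS_TACHO = 4.0  # Hz


def _band_power(f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    m = (f >= lo) & (f < hi)
    if not np.any(m):
        return 0.0
    return float(np.trapezoid(psd[m], f[m]))


def _levinson(r: np.ndarray, order: int) -> np.ndarray | None:
    """AR coefficients [1, a1..a_order] from the autocorrelation sequence."""
    a = np.array([1.0])
    e = r[0]
    if e <= 0:
        return None
    for m in range(1, order + 1):
        acc = r[m] + np.dot(a[1:], r[m - 1:0:-1])
        k = -acc / e
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        e *= (1.0 - k * k)
        if e <= 0:
            return None
    return a


def resample_tachogram(t: np.ndarray, rr: np.ndarray,
                       lo: float, hi: float) -> np.ndarray | None:
    """Cubic-spline resampling of RR(t) onto a 4-Hz grid inside [lo, hi)."""
    if t.size < 4:
        return None
    g0 = max(lo, t[0])
    g1 = min(hi, t[-1])
    grid = np.arange(g0, g1, 1.0 / FS_TACHO)
    if grid.size < 32:
        return None
    return CubicSpline(t, rr)(grid)


def spectral_features(t: np.ndarray, rr: np.ndarray, lo: float, hi: float,
                      n_valid: int) -> np.ndarray:
    """Classic + boundary-adapted band powers and the AR HF-pole (12 values).

    ``t, rr`` are all beats in the window with invalid beats already
    linearly interpolated; ``n_valid`` gates the computation.
    """
    out = np.full(12, np.nan)
    if n_valid < 60:
        return out
    x = resample_tachogram(t, rr, lo, hi)
    if x is None:
        return out
    x = x - x.mean()
    nper = min(480, x.size)
    f, psd = welch(x, fs=FS_TACHO, window="hann", nperseg=nper,
                   noverlap=nper // 2, detrend="constant")

    p_vlf = _band_power(f, psd, *VLF_BAND)
    p_lf = _band_power(f, psd, *LF_BAND)
    p_hf = _band_power(f, psd, *HF_BAND)
    def _ratio(p_num: float, p_den: float) -> float:
        # both bands at the floor (degenerate flat spectrum): undefined
        if p_num <= LN_FLOOR and p_den <= LN_FLOOR:
            return np.nan
        return (p_num + LN_FLOOR) / (p_den + LN_FLOOR)

    out[0] = math.log(p_vlf + LN_FLOOR)
    out[1] = math.log(p_lf + LN_FLOOR)
    out[2] = math.log(p_hf + LN_FLOOR)
    out[3] = _ratio(p_lf, p_hf)

    # respiratory peak inside the HF band
    hf_mask = (f >= HF_BAND[0]) & (f < HF_BAND[1])
    resp_freq = np.nan
    if np.any(hf_mask) and np.any(psd[hf_mask] > 0):
        fi = np.flatnonzero(hf_mask)[np.argmax(psd[hf_mask])]
        resp_freq = float(f[fi])
        p_resp = _band_power(f, psd, resp_freq - 0.015, resp_freq + 0.015)
        out[8] = resp_freq
        out[9] = math.log(p_resp + LN_FLOOR)

    # boundary-adapted bands: HF re-centred on the respiratory peak
    if np.isfinite(resp_freq):
        hf_lo = min(max(resp_freq - 0.1, 0.1), 0.5)
        hf_hi = min(max(resp_freq + 0.1, 0.1), 0.5)
        p_hf_a = _band_power(f, psd, hf_lo, hf_hi)
        p_lf_a = _band_power(f, psd, 0.04, hf_lo)
        p_vlf_a = _band_power(f, psd, *VLF_BAND)
        out[4] = math.log(p_vlf_a + LN_FLOOR)
        out[5] = math.log(p_lf_a + LN_FLOOR)
        out[6] = math.log(p_hf_a + LN_FLOOR)
        out[7] = _ratio(p_lf_a, p_hf_a)

    # AR(9) pole with the largest modulus whose angle lies in the HF band
    nlags = 9
    if x.size > 4 * nlags:
        r = np.array([np.dot(x[:x.size - k], x[k:]) / x.size
                      for k in range(nlags + 1)])
        a = _levinson(r, nlags)
        if a is not None:
            poles = np.roots(a)
            ang = np.abs(np.angle(poles))
            lo_a = 2 * math.pi * HF_BAND[0] / FS_TACHO
            hi_a = 2 * math.pi * HF_BAND[1] / FS_TACHO
            in_band = (ang >= lo_a) & (ang <= hi_a)
            if np.any(in_band):
                mod = np.abs(poles)
                best = np.flatnonzero(in_band)[np.argmax(mod[in_band])]
                out[10] = float(ang[best])
                out[11] = float(mod[best])
    return out


# ---------------------------------------------------------------------------
# Entropy and regularity families


def sample_entropy(x: np.ndarray, m: int, r: float) -> float:
    """SampEn(m, r): -ln(A/B), Chebyshev distance, self-matches excluded."""
    full, restricted = _kernels.template_match_counts(
        np.ascontiguousarray(x, dtype=float), m + 1, float(r))
    a, b = full[m], restricted[m - 1]
    if a == 0 or b == 0:
        return np.nan
    return float(-math.log(a / b))


def mse_features(rr510: np.ndarray) -> np.ndarray:
    """Multiscale sample entropy, m in {1, 2}, scales 1..10 (20 values).

    r is 0.2 x SD of the scale-1 segment and frozen across scales; scales
    whose coarse-grained series has fewer than 30 points are missing.
    """
    out = np.full(20, np.nan)
    rr510 = np.asarray(rr510, dtype=float)
    sd = rr510.std()
    if rr510.size < 60 or sd == 0:
        return out
    r = 0.2 * sd
    for si, tau in enumerate(MSE_SCALES):
        n_cg = rr510.size // tau
        if n_cg < 30:
            continue
        cg = rr510[:n_cg * tau].reshape(n_cg, tau).mean(axis=1)
        out[si] = sample_entropy(cg, 1, r)
        out[10 + si] = sample_entropy(cg, 2, r)
    return out


def symbolic_entropy(rr: np.ndarray) -> float:
    """SampEn(m=2) of the binary increase/decrease symbol string.

    Zero differences map to '0' (the project-wide '-' convention); exact
    matching is realized as Chebyshev tolerance r = 0.5 on {0, 1} symbols.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 50:
        return np.nan
    sym = (np.diff(rr) > 0).astype(float)
    if np.all(sym == sym[0]):
        return np.nan
    return sample_entropy(sym, 2, 0.5)


def _sign_sequence(rr: np.ndarray) -> np.ndarray:
    return (np.diff(rr) > 0).astype(np.int8)


def phase_coordination_features(rr: np.ndarray) -> np.ndarray:
    """Fractions of beats inside back-to-back repeated sign patterns.

    Patterns of length 3..8 repeating exactly twice feed the short-range
    fraction; three or more repetitions feed the long-range fraction.
    """
    out = np.full(2, np.nan)
    rr = np.asarray(rr, dtype=float)
    if rr.size < 50:
        return out
    cov2, cov3 = _kernels.coordination_masks(_sign_sequence(rr))
    cov2 = cov2.astype(bool)
    cov3 = cov3.astype(bool)
    out[0] = float(np.mean(cov2 & ~cov3))
    out[1] = float(np.mean(cov3))
    return out


def phase_sync_features(t: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """n:2 cardiorespiratory synchronization rates and episode statistics.

    rate_n for n in {6,7,8,9}, the dominant ratio (ties to the smaller n),
    the mean synchronized-episode duration in seconds, and the fraction of
    the window spent in episodes of at least 30 s.
    """
    out = np.full(7, np.nan)
    rr = np.asarray(rr, dtype=float)
    if rr.size < 60:
        return out
    masks = _kernels.sync_masks(_sign_sequence(rr)).astype(bool)
    rates = masks.mean(axis=1)
    out[0:4] = rates
    out[4] = float(SYNC_RATIOS[int(np.argmax(rates))])
    union = masks.any(axis=0)
    # episodes: maximal runs of synchronized sign positions, in seconds
    durations = []
    in_ep = False
    start = 0
    for k in range(union.size):
        if union[k] and not in_ep:
            in_ep, start = True, k
        elif not union[k] and in_ep:
            in_ep = False
            durations.append(float(t[k] - t[start]))
    if in_ep:
        durations.append(float(t[union.size] - t[start]))
    span = float(t[-1] - t[0])
    if durations:
        d = np.asarray(durations)
        out[5] = float(d.mean())
        out[6] = float(d[d >= 30.0].sum() / span) if span > 0 else np.nan
    else:
        out[5] = 0.0
        out[6] = 0.0
    return out


def higuchi_fd(rr: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension of the z-scored RR sequence."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 100:
        return np.nan
    sd = rr.std()
    if sd == 0:
        return np.nan
    z = (rr - rr.mean()) / sd
    lengths = _kernels.higuchi_lengths(z, k_max)
    k = np.arange(1, k_max + 1, dtype=float)
    ok = np.isfinite(lengths) & (lengths > 0)
    if ok.sum() < 3:
        return np.nan
    return float(-np.polyfit(np.log(k[ok]), np.log(lengths[ok]), 1)[0])


# ---------------------------------------------------------------------------
# Teager-energy morphology


def _transition_points(x: np.ndarray) -> np.ndarray:
    """Indices where the sign of the first difference of the 3-point moving
    average changes (zero differences count as negative)."""
    if x.size < 5:
        return np.empty(0, dtype=int)
    ma = np.convolve(x, np.ones(3) / 3.0, mode="valid")
    s = (np.diff(ma) > 0).astype(np.int8)
    return np.flatnonzero(s[1:] != s[:-1]) + 2  # index back into x coordinates


def _local_maxima(x: np.ndarray) -> np.ndarray:
    if x.size < 3:
        return np.empty(0, dtype=int)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def _event_stats(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """pct, interval mean/sd, amplitude mean/sd of an event index set."""
    out = np.full(5, np.nan)
    out[0] = 100.0 * idx.size / x.size
    if idx.size >= 2:
        ivals = np.diff(idx).astype(float)
        out[1] = ivals.mean()
        out[2] = ivals.std(ddof=1) if ivals.size >= 2 else np.nan
    if idx.size >= 1:
        amp = x[idx]
        out[3] = amp.mean()
        out[4] = amp.std(ddof=1) if amp.size >= 2 else np.nan
    return out


def teager_features(rr: np.ndarray) -> np.ndarray:
    """Mean Teager energy + transition/maxima morphology (21 values).

    The Teager operator psi(x_i) = x_i^2 - x_{i-1} x_{i+1} is applied to the
    z-scored IBI sequence; morphology statistics are computed on that
    sequence and on its first intrinsic mode function.
    """
    out = np.full(21, np.nan)
    rr = np.asarray(rr, dtype=float)
    if rr.size < 100:
        return out
    sd = rr.std()
    # constant segment: psi is identically zero (x^2 - x*x); event statistics
    # stay missing since there are no transitions or maxima
    z = (rr - rr.mean()) / sd if sd > 0 else rr - rr.mean()
    psi = z[1:-1] ** 2 - z[:-2] * z[2:]
    out[0] = float(psi.mean())
    imf = first_imf(z)
    for k, rep in enumerate((z, imf)):
        trans = _transition_points(rep)
        maxima = _local_maxima(rep)
        ts = _event_stats(rep, trans)
        ms = _event_stats(rep, maxima)
        base = 1 + 10 * k
        out[base + 0] = ts[0]          # % transition points
        out[base + 1] = ms[0]          # % maxima
        out[base + 2:base + 4] = ts[1:3]   # transition interval mean/sd
        out[base + 4:base + 6] = ms[1:3]   # maxima interval mean/sd
        out[base + 6:base + 8] = ts[3:5]   # amplitude at transitions
        out[base + 8:base + 10] = ms[3:5]  # amplitude at maxima
    return out


# ---------------------------------------------------------------------------
# Arousal-probability surrogate


def arousal_features(series: IBISeries, grid: EpochGrid, epoch: int,
                     window_len_s: float = 270.0) -> np.ndarray:
    """Summary statistics of a heart-rate-surge arousal-probability signal.

    This is a deliberately simple surrogate probability model: for every
    10-s step inside the window, the step's mean HR is z-scored against the
    trailing 120 s and squashed through a logistic centred at z = 2.  The
    five summaries (max, mean, median, min, SD) match the downstream
    contract of a per-window probability signal.
    """
    out = np.full(5, np.nan)
    c = grid.center_of(epoch)
    lo = max(0.0, c - window_len_s / 2.0)
    hi = min(series.duration_s, c + window_len_s / 2.0)
    t = series.beat_times_s
    rr = series.rr_ms
    valid = series.valid
    probs = []
    step = lo
    while step + 10.0 <= hi:
        if step >= 120.0:
            i0, i1 = np.searchsorted(t, [step, step + 10.0])
            j0 = np.searchsorted(t, step - 120.0)
            m_step = valid[i0:i1]
            m_base = valid[j0:i0]
            if m_step.sum() >= 3 and m_base.sum() >= 20:
                hr_step = 60000.0 / rr[i0:i1][m_step]
                hr_base = 60000.0 / rr[j0:i0][m_base]
                sd = max(hr_base.std(), 0.1)  # 0.1 bpm floor for flat baselines
                zval = (hr_step.mean() - hr_base.mean()) / sd
                zval = min(max(zval, -50.0), 50.0)
                probs.append(1.0 / (1.0 + math.exp(-(zval - 2.0) / 0.5)))
        step += 10.0
    if len(probs) < 3:
        return out
    p = np.asarray(probs)
    return np.array([p.max(), p.mean(), np.median(p), p.min(), p.std()])


# ---------------------------------------------------------------------------
# Visibility graphs


def nvg_edges(t: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """Edge list of the natural visibility graph (for auditing/tests)."""
    adj = _kernels.nvg_adjacency(np.ascontiguousarray(t, dtype=float),
                                 np.ascontiguousarray(y, dtype=float))
    iu, ju = np.nonzero(np.triu(adj, 1))
    return list(zip(iu.tolist(), ju.tolist()))


def _degree_stats(deg: np.ndarray) -> np.ndarray:
    """mean, sd, power-law slope, % deg<=3, % deg>=10."""
    out = np.full(5, np.nan)
    out[0] = deg.mean()
    out[1] = deg.std(ddof=1) if deg.size >= 2 else np.nan
    vals, counts = np.unique(deg[deg > 0], return_counts=True)
    if vals.size >= 2:
        out[2] = float(np.polyfit(np.log(vals.astype(float)),
                                  np.log(counts.astype(float)), 1)[0])
    out[3] = 100.0 * np.mean(deg <= 3)
    out[4] = 100.0 * np.mean(deg >= 10)
    return out


def visibility_features(t: np.ndarray, rr: np.ndarray) -> np.ndarray:
    """NVG statistics (8) + difference-VG degree statistics (5)."""
    out = np.full(13, np.nan)
    rr = np.asarray(rr, dtype=float)
    if rr.size < 50:
        return out
    adj = _kernels.nvg_adjacency(np.ascontiguousarray(t, dtype=float),
                                 np.ascontiguousarray(rr))
    deg = adj.sum(axis=1).astype(np.int64)
    # degree assortativity: Pearson correlation of endpoint degrees
    iu, ju = np.nonzero(np.triu(adj, 1))
    if iu.size >= 2:
        a = np.concatenate([deg[iu], deg[ju]]).astype(float)
        b = np.concatenate([deg[ju], deg[iu]]).astype(float)
        if a.std() > 0 and b.std() > 0:
            out[0] = float(np.corrcoef(a, b)[0, 1])
    af = adj.astype(np.float32)
    closed = ((af @ af) * af).sum(axis=1)  # 2 x triangles per node
    denom = (deg * (deg - 1)).astype(np.float32)
    clust = np.zeros_like(closed)
    nz = denom > 0
    clust[nz] = closed[nz] / denom[nz]
    out[1] = float(clust.mean())
    out[2] = float(clust.std(ddof=1)) if clust.size >= 2 else np.nan
    out[3:8] = _degree_stats(deg)
    d = np.diff(rr)
    adj2 = _kernels.nvg_adjacency(np.ascontiguousarray(t[1:], dtype=float),
                                  np.ascontiguousarray(d))
    out[8:13] = _degree_stats(adj2.sum(axis=1).astype(np.int64))
    return out


# ---------------------------------------------------------------------------
# Full extraction


def _interpolated_rr(series: IBISeries) -> np.ndarray:
    """RR with invalid beats linearly interpolated (spectral path only)."""
    rr = series.rr_ms.copy()
    if series.valid.all() or not series.valid.any():
        return rr
    t = series.beat_times_s
    inval = ~series.valid
    rr[inval] = np.interp(t[inval], t[series.valid], rr[series.valid])
    return rr


def extract_all(series: IBISeries, grid: EpochGrid,
                spec: WindowSpec | None = None) -> FeatureTable:
    """Compute the full 132-column feature table for every epoch.

    A family is missing for an epoch when its (possibly truncated) window
    retains less than half the nominal length or its valid-beat fraction is
    below ``spec.min_valid_fraction``.
    """
    spec = spec or WindowSpec()
    n_ep = grid.n_epochs
    values = np.full((n_ep, N_FEATURES), np.nan)
    vfrac = np.zeros(n_ep)
    rr_interp = _interpolated_rr(series)
    dur = series.duration_s

    sl = {fam: family_slice(fam) for fam in
          ("basic", "variability", "percentiles", "dfa", "spectral",
           "spectral_adapted", "resp_pole", "mse", "symbolic",
           "phase_coordination", "phase_sync", "higuchi", "teager",
           "arousal", "visibility")}

    for e in range(n_ep):
        c = grid.center_of(e)

        def usable(length: float) -> bool:
            return _window_coverage(dur, c, length) >= spec.min_coverage_fraction

        # default 270-s window
        if usable(spec.default_len_s):
            t_w, rr_w, n_tot, n_val = window_slice(series, grid, e, spec.default_len_s)
            vfrac[e] = n_val / n_tot if n_tot else 0.0
            if n_tot and n_val / n_tot >= spec.min_valid_fraction:
                bv = basic_and_variability_features(rr_w)
                values[e, sl["basic"]] = bv[:4]
                values[e, sl["variability"]] = bv[4:]
                values[e, sl["percentiles"]] = percentile_features(rr_w)
                values[e, sl["dfa"]] = dfa_features(rr_w, series, grid, e, spec)
                lo = max(0.0, c - spec.default_len_s / 2.0)
                hi = min(dur, c + spec.default_len_s / 2.0)
                i0, i1 = np.searchsorted(series.beat_times_s, [lo, hi], side="left")
                spc = spectral_features(series.beat_times_s[i0:i1],
                                        rr_interp[i0:i1], lo, hi, n_val)
                values[e, sl["spectral"]] = spc[0:4]
                values[e, sl["spectral_adapted"]] = spc[4:8]
                values[e, sl["resp_pole"]] = spc[8:12]
                values[e, sl["symbolic"]] = symbolic_entropy(rr_w)
                values[e, sl["phase_coordination"]] = phase_coordination_features(rr_w)
                values[e, sl["phase_sync"]] = phase_sync_features(t_w, rr_w)
                values[e, sl["higuchi"]] = higuchi_fd(rr_w)
                values[e, sl["teager"]] = teager_features(rr_w)
                values[e, sl["arousal"]] = arousal_features(
                    series, grid, e, spec.default_len_s)
                values[e, sl["visibility"]] = visibility_features(t_w, rr_w)

        # 510-s MSE window
        if usable(spec.mse_len_s):
            _, rr_m, n_tot, n_val = window_slice(series, grid, e, spec.mse_len_s)
            if n_tot and n_val / n_tot >= spec.min_valid_fraction:
                values[e, sl["mse"]] = mse_features(rr_m)

    return FeatureTable(values=values, valid_beat_fraction=vfrac)
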