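"""Vital-rate computation and agreement summaries.

Breathing rates come from the autocorrelation peak lag, heart rates from
peak-to-peak intervals: on ECG after a Symlet-4 stationary-wavelet QRS
emphasis, on radar phase after amplitude-envelope normalization.  Rates
from multiple selected bins are aggregated by the median.  Undefined rates
are returned as ``nan``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .epoching import WindowGrid, make_rate_windows, merge_selections
from .processing import RangeTimeMatrix, all_phases
from .selection import SelectionCriteria, SelectionMask, band_filter

# Symlet-4 decomposition low-pass filter (orthonormal, sums to sqrt(2)).
SYM4_DEC_LO = np.array([
    -0.07576571478927333, -0.02963552764599851, 0.49761866763201545,
    0.8037387518059161, 0.29785779560527736, -0.09921954357684722,
    -0.012603967262037833, 0.0322231006040427,
])
SYM4_DEC_HI = np.array([
    (-1.0) ** k * c for k, c in enumerate(SYM4_DEC_LO[::-1])
])


@dataclass(frozen=True)
class RateSettings:
    """Definedness floors and peak-finding parameters (not from physiology)."""

    min_autocorr: float = 0.3
    refractory_s: float = 0.3
    min_beat_fraction: float = 0.5
    envelope_smooth_s: float = 0.5


@dataclass(frozen=True)
class ErrorSummary:
    mae: float
    mape: float
    pct_within_1bpm: float
    mean_diff: float
    loa_lower: float
    loa_upper: float
    n_windows: int

    def to_dict(self) -> dict:
        return {
            "mae_bpm": self.mae, "mape_pct": self.mape,
            "pct_within_1bpm": self.pct_within_1bpm,
            "mean_diff_bpm": self.mean_diff,
            "loa_lower_bpm": self.loa_lower, "loa_upper_bpm": self.loa_upper,
            "n_windows": self.n_windows,
        }


# ---------------------------------------------------------------------------
# Single-window rate estimators
# ---------------------------------------------------------------------------


def autocorr_rate(series: np.ndarray, fs: float,
                  band_bpm: tuple[float, float] = (10.0, 22.0),
                  settings: RateSettings | None = None) -> float:
    """Rate [BPM] from the best autocorrelation lag within the band.

    The lag search is restricted to the band's period range; the peak lag is
    refined by parabolic interpolation.  Returns ``nan`` when the best
    correlation is below the definedness floor or the series is flat.
    """
    settings = settings or RateSettings()
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    if len(x) < 4 or np.ptp(x) == 0:
        return np.nan
    acf = signal.correlate(x, x, mode="full")[len(x) - 1:]
    if acf[0] <= 0:
        return np.nan
    acf = acf / acf[0]
    lo_lag = int(np.floor(fs * 60.0 / band_bpm[1]))
    hi_lag = int(np.ceil(fs * 60.0 / band_bpm[0]))
    lo_lag = max(lo_lag, 1)
    hi_lag = min(hi_lag, len(acf) - 1)
    if hi_lag <= lo_lag:
        return np.nan
    seg = acf[lo_lag : hi_lag + 1]
    best = float(np.max(seg))
    if best < settings.min_autocorr:
        return np.nan
    # subharmonic guard: a lag of 2T correlates as well as T for periodic
    # signals; prefer the shortest lag within 90% of the band maximum,
    # provided it is a local maximum
    candidates = np.flatnonzero(seg >= 0.9 * best)
    k = int(candidates[0])
    for c in candidates:
        lag_c = lo_lag + int(c)
        if 0 < lag_c < len(acf) - 1 and acf[lag_c] >= max(acf[lag_c - 1], acf[lag_c + 1]):
            k = int(c)
            break
    lag = lo_lag + k
    if 0 < lag < len(acf) - 1:  # parabolic refinement
        y0, y1, y2 = acf[lag - 1], acf[lag], acf[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag = lag + 0.5 * (y0 - y2) / denom
    return 60.0 * fs / lag


def swt_detail(series: np.ndarray, fs: float, level: int | None = None) -> np.ndarray:
    """Symlet-4 stationary (a trous, undecimated) detail coefficients.

    The level is chosen so the detail band covers roughly 10-25 Hz where
    QRS energy concentrates (level ~ log2(fs / 25)).  Circular convolution;
    the constant group delay is irrelevant for interval-based rates.
    """
    x = np.asarray(series, dtype=float)
    if level is None:
        level = max(1, int(round(np.log2(fs / 25.0))))
    approx = x
    detail = np.zeros_like(x)
    for j in range(level):
        hole = 2 ** j
        lo = np.zeros(len(SYM4_DEC_LO) * hole)
        hi = np.zeros_like(lo)
        lo[::hole] = SYM4_DEC_LO / np.sqrt(2.0)
        hi[::hole] = SYM4_DEC_HI / np.sqrt(2.0)
        n = len(x)
        f_a = np.fft.rfft(approx)
        detail = np.fft.irfft(f_a * np.fft.rfft(hi, n), n)
        approx = np.fft.irfft(f_a * np.fft.rfft(lo, n), n)
    return detail


def _refine_peaks(y: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample peak positions by parabolic interpolation (the 50 ms
    frame grid otherwise quantizes beat intervals by several BPM)."""
    refined = peaks.astype(float)
    for i, p in enumerate(peaks):
        if 0 < p < len(y) - 1:
            y0, y1, y2 = y[p - 1], y[p], y[p + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                refined[i] = p + 0.5 * (y0 - y2) / denom
    return refined


def _rate_from_peaks(y: np.ndarray, peaks: np.ndarray, fs: float,
                     window_s: float, settings: RateSettings) -> float:
    min_beats = settings.min_beat_fraction * 40.0 * window_s / 60.0
    if len(peaks) < max(2, min_beats):
        return np.nan
    intervals = np.diff(_refine_peaks(y, peaks)) / fs
    return 60.0 / float(np.median(intervals))


def ecg_heart_rate(ecg: np.ndarray, fs: float,
                   settings: RateSettings | None = None) -> float:
    """Heart rate [BPM] from an ECG trace via SWT QRS emphasis.

    Squared Symlet-4 detail coefficients are smoothed and peak-found with a
    0.3 s refractory period; the rate is 60 / median(peak-to-peak interval).
    """
    settings = settings or RateSettings()
    x = np.asarray(ecg, dtype=float)
    if len(x) < int(fs) or np.ptp(x) == 0:
        return np.nan
    energy = swt_detail(x, fs) ** 2
    win = max(1, int(0.05 * fs))
    energy = np.convolve(energy, np.ones(win) / win, mode="same")
    floor = 0.2 * np.percentile(energy, 99)
    peaks, _ = signal.find_peaks(
        energy, distance=max(1, int(settings.refractory_s * fs)), height=floor)
    return _rate_from_peaks(energy, peaks, fs, len(x) / fs, settings)


def normalize_envelope(series: np.ndarray, fs: float,
                       settings: RateSettings | None = None) -> np.ndarray:
    """Divide by the smoothed analytic-signal envelope to equalize beats.

    Stand-in for the cited amplitude-normalization procedure; swap via this
    interface if a faithful reimplementation is needed.
    """
    settings = settings or RateSettings()
    x = np.asarray(series, dtype=float)
    env = np.abs(signal.hilbert(x - x.mean()))
    win = max(1, int(settings.envelope_smooth_s * fs))
    env = np.convolve(env, np.ones(win) / win, mode="same")
    floor = 0.1 * np.median(env) if np.median(env) > 0 else 1.0
    return (x - x.mean()) / np.maximum(env, floor)


def radar_heart_rate(series: np.ndarray, fs: float,
                     settings: RateSettings | None = None) -> float:
    """Heart rate [BPM] from a heartbeat-band-filtered radar phase series.

    A coarse autocorrelation estimate over the 40-200 BPM band sets the
    peak-finding refractory period (0.6 beat periods, never below the
    configured floor); beats are then located by peak finding and the rate
    is 60 / median(peak-to-peak interval).  The window is undefined when
    the coarse estimate is undefined, too few beats are found, or the
    peak-based rate disagrees with the coarse estimate by more than 20%
    (guards against spurious peak insertions/deletions).
    """
    settings = settings or RateSettings()
    x = np.asarray(series, dtype=float)
    if len(x) < int(fs) or np.ptp(x) == 0:
        return np.nan
    coarse = autocorr_rate(x, fs, (40.0, 200.0), settings)
    if not np.isfinite(coarse):
        return np.nan
    refractory = max(settings.refractory_s, 0.6 * 60.0 / coarse)
    peaks, _ = signal.find_peaks(
        x, distance=max(1, int(refractory * fs)), prominence=0.5 * np.std(x))
    rate = _rate_from_peaks(x, peaks, fs, len(x) / fs, settings)
    if not np.isfinite(rate) or abs(rate - coarse) > 0.2 * coarse:
        return np.nan
    return rate


def aggregate_bins(per_bin_rates) -> float:
    """Median over the defined per-bin rates; ``nan`` if none are defined."""
    rates = np.asarray(per_bin_rates, dtype=float)
    rates = rates[np.isfinite(rates)]
    if len(rates) == 0:
        return np.nan
    return float(np.median(rates))


# ---------------------------------------------------------------------------
# Recording-level rate series
# ---------------------------------------------------------------------------


def rate_series(matrix: RangeTimeMatrix, mask: SelectionMask,
                grid: WindowGrid | None = None,
                criteria: SelectionCriteria | None = None,
                settings: RateSettings | None = None,
                *, single_best_bin: bool = False) -> pd.DataFrame:
    """Per-60 s-window vital rates from every selected bin.

    The 15 s mask is quorum-merged to the 60 s grid; rates are computed per
    selected bin and aggregated by the median.  With ``single_best_bin``
    only the selected bin with the highest in-band signal power is used
    (single-bin baseline for comparison).

    Returns a DataFrame with columns window_start_s, rate_bpm, n_bins_used.
    """
    grid = grid or WindowGrid()
    criteria = criteria or SelectionCriteria()
    settings = settings or RateSettings()
    if matrix.level != "frame":
        raise ValueError("rate_series expects a frame-level matrix")
    fs = matrix.fs
    vital = mask.vital
    merged = merge_selections(mask.selected, grid)
    windows = make_rate_windows(mask.selected.shape[1], grid)

    phases = all_phases(matrix)
    filtered = band_filter(phases, vital, fs, criteria)
    band_bpm = (criteria.breathing_band_bpm if vital == "breathing"
                else criteria.heartbeat_band_bpm)

    rows = []
    for w, win in enumerate(windows):
        sl = win.sample_slice(fs)
        bins = np.flatnonzero(merged[:, w])
        per_bin = {}
        for b in bins:
            x = filtered[b, sl]
            if vital == "breathing":
                r = autocorr_rate(x, fs, band_bpm, settings)
            else:
                r = radar_heart_rate(x, fs, settings)
            per_bin[int(mask.bin_indices[b])] = r
        defined = {k: v for k, v in per_bin.items() if np.isfinite(v)}
        if single_best_bin and defined:
            powers = {k: float(np.var(filtered[np.flatnonzero(mask.bin_indices == k)[0], sl]))
                      for k in defined}
            best = max(powers, key=powers.get)
            rate, n_used = defined[best], 1
        else:
            rate, n_used = aggregate_bins(list(per_bin.values())), len(defined)
        rows.append({"window_start_s": win.start_s, "rate_bpm": rate,
                     "n_bins_used": n_used})
    return pd.DataFrame(rows, columns=["window_start_s", "rate_bpm", "n_bins_used"])


def reference_rate_series(trace: np.ndarray, fs: float, vital: str,
                          n_short_windows: int,
                          grid: WindowGrid | None = None,
                          criteria: SelectionCriteria | None = None,
                          settings: RateSettings | None = None) -> pd.DataFrame:
    """Belt/ECG reference rates on the same 60 s grid as the radar."""
    grid = grid or WindowGrid()
    criteria = criteria or SelectionCriteria()
    settings = settings or RateSettings()
    windows = make_rate_windows(n_short_windows, grid)
    x = np.asarray(trace, dtype=float)
    rows = []
    for win in windows:
        seg = x[win.sample_slice(fs)]
        if vital == "breathing":
            r = autocorr_rate(seg, fs, criteria.breathing_band_bpm, settings)
        else:
            r = ecg_heart_rate(seg, fs, settings)
        rows.append({"window_start_s": win.start_s, "rate_bpm": r})
    return pd.DataFrame(rows, columns=["window_start_s", "rate_bpm"])


def error_summary(f_ref: np.ndarray, f_radar: np.ndarray) -> ErrorSummary:
    """MAE, MAPE, +-1 BPM agreement and Bland-Altman limits.

    Only windows defined in both series are compared; the difference sign
    convention is reference minus radar.  Zero reference rates are excluded
    from the MAPE.
    """
    ref = np.asarray(f_ref, dtype=float)
    rad = np.asarray(f_radar, dtype=float)
    if ref.shape != rad.shape:
        raise ValueError("rate series must have equal length")
    ok = np.isfinite(ref) & np.isfinite(rad)
    if not np.any(ok):
        raise ValueError("no windows with both rates defined")
    ref, rad = ref[ok], rad[ok]
    diff = ref - rad
    mae = float(np.mean(np.abs(diff)))
    nz = ref != 0
    mape = float(100.0 * np.mean(np.abs(diff[nz]) / ref[nz])) if np.any(nz) else np.nan
    pct1 = float(100.0 * np.mean(np.abs(diff) < 1.0))
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff))
    return ErrorSummary(
        mae=mae, mape=mape, pct_within_1bpm=pct1, mean_diff=mean_diff,
        loa_lower=mean_diff - 1.96 * sd, loa_upper=mean_diff + 1.96 * sd,
        n_windows=int(np.sum(ok)),
    )
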