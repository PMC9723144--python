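"""DPSS multitaper spectral estimation.

Power spectra, spectrograms, band powers, theta peak frequency and the
theta-power-vs-running-speed correlation. All estimators average over
orthogonal Slepian tapers (default time-bandwidth NW = 3, K = 5 tapers) on
2 s segments, the common defaults of the classic multitaper toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy import stats as sstats

from .config import AnalysisConfig
from .containers import IntervalSet

__all__ = [
    "Psd", "Spectrogram", "multitaper_psd", "spectrogram",
    "relative_band_power", "band_power", "theta_peak_frequency",
    "theta_speed_correlation", "mt_coherence", "dpss_tapers",
    "segment_starts", "tapered_fft",
]


@lru_cache(maxsize=32)
def dpss_tapers(n: int, nw: float = 3.0, k: int = 5) -> np.ndarray:
    """Unit-energy DPSS tapers, shape (k, n)."""
    tapers = sps.windows.dpss(n, nw, Kmax=k)
    tapers = tapers / np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))
    return tapers


@dataclass
class Psd:
    freqs: np.ndarray          # Hz, strictly increasing
    power: np.ndarray          # units^2/Hz, >= 0
    nw: float
    k: int
    n_segments: int

    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class Spectrogram:
    times: np.ndarray          # window centers, s
    freqs: np.ndarray
    power: np.ndarray          # (n_times, n_freqs)


# ----------------------------------------------------------------------
def segment_starts(n: int, fs: float, seg_samples: int,
                   intervals: Optional[IntervalSet] = None) -> np.ndarray:
    """Start indices of non-overlapping segments fully inside `intervals`
    (whole record when None)."""
    if intervals is None or len(intervals) == 0:
        lims = [(0, n)]
    else:
        lims = [(int(np.ceil(s * fs)), int(np.floor(e * fs)))
                for s, e, _ in intervals]
    out = []
    for a, b in lims:
        b = min(b, n)
        n_seg = (b - a) // seg_samples
        out.extend(a + seg_samples * np.arange(n_seg))
    return np.asarray(out, dtype=int)


def _gather_segments(x: np.ndarray, starts: np.ndarray, seg: int) -> np.ndarray:
    if len(starts) == 0:
        raise ValueError("no complete segment fits inside the given intervals")
    return x[starts[:, None] + np.arange(seg)[None, :]]


def tapered_fft(segs: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """rfft of each (mean-subtracted) segment under each taper.

    segs (S, n), tapers (K, n) -> complex (S, K, F).
    """
    from scipy import fft as sfft

    segs = segs - segs.mean(axis=-1, keepdims=True)
    return sfft.rfft(segs[:, None, :] * tapers[None, :, :], axis=-1)


def _psd_from_fft(X: np.ndarray, fs: float, n: int) -> np.ndarray:
    """One-sided PSD averaged over segments and tapers."""
    S = (np.abs(X) ** 2).mean(axis=(0, 1)) / fs
    S[1:] *= 2.0
    if n % 2 == 0:
        S[-1] /= 2.0
    return S


# ----------------------------------------------------------------------
def multitaper_psd(x: np.ndarray, fs: float,
                   intervals: Optional[IntervalSet] = None,
                   config: Optional[AnalysisConfig] = None,
                   seg_len: Optional[float] = None,
                   nw: Optional[float] = None, k: Optional[int] = None,
                   fmax: Optional[float] = None) -> Psd:
    """Multitaper PSD averaged over non-overlapping segments drawn from the
    given intervals; each segment is mean-subtracted before tapering."""
    cfg = config or AnalysisConfig()
    seg_len = seg_len or cfg.seg_len
    nw = nw or cfg.mt_nw
    k = k or cfg.mt_k
    fmax = cfg.psd_fmax if fmax is None else fmax
    x = np.asarray(x, dtype=float)
    seg = int(round(seg_len * fs))
    starts = segment_starts(len(x), fs, seg, intervals)
    if len(starts) == 0:
        raise ValueError("intervals shorter than one segment")
    X = tapered_fft(_gather_segments(x, starts, seg), dpss_tapers(seg, nw, k))
    S = _psd_from_fft(X, fs, seg)
    freqs = np.fft.rfftfreq(seg, 1.0 / fs)
    m = freqs <= fmax
    return Psd(freqs=freqs[m], power=S[m], nw=nw, k=k, n_segments=len(starts))


def spectrogram(x: np.ndarray, fs: float,
                config: Optional[AnalysisConfig] = None,
                window: Optional[float] = None, step: Optional[float] = None,
                nw: Optional[float] = None, k: Optional[int] = None,
                fmax: Optional[float] = None,
                chunk: int = 512) -> Spectrogram:
    """Sliding-window multitaper power (default 2 s window, 10 ms step)."""
    cfg = config or AnalysisConfig()
    window = window or cfg.spectrogram_window
    step = step or cfg.spectrogram_step
    nw = nw or cfg.mt_nw
    k = k or cfg.mt_k
    fmax = cfg.psd_fmax if fmax is None else fmax
    x = np.asarray(x, dtype=float)
    win = int(round(window * fs))
    hop = max(1, int(round(step * fs)))
    if len(x) < win:
        raise ValueError("signal shorter than one window")
    starts = np.arange(0, len(x) - win + 1, hop)
    tapers = dpss_tapers(win, nw, k)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    m = freqs <= fmax
    rows = []
    for i in range(0, len(starts), chunk):
        segs = _gather_segments(x, starts[i:i + chunk], win)
        X = tapered_fft(segs, tapers)
        S = (np.abs(X) ** 2).mean(axis=1) / fs
        S[:, 1:] *= 2.0
        if win % 2 == 0:
            S[:, -1] /= 2.0
        rows.append(S[:, m])
    power = np.vstack(rows)
    times = (starts + win / 2.0) / fs
    return Spectrogram(times=times, freqs=freqs[m], power=power)


# ----------------------------------------------------------------------
def band_power(psd: Psd, band: Tuple[float, float]) -> float:
    """Integrated power in [lo, hi] (closed band edges on the grid)."""
    lo, hi = band
    m = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not m.any():
        raise ValueError(f"no PSD bins inside band {band}")
    return float(np.sum(psd.power[m]) * psd.df())


def relative_band_power(psd: Psd, band: Tuple[float, float],
                        fmax: Optional[float] = None) -> float:
    """Band power as a fraction of total power over [0, fmax]."""
    fmax = psd.freqs[-1] if fmax is None else fmax
    total = band_power(psd, (0.0, fmax))
    if total <= 0:
        raise ValueError("degenerate spectrum: zero total power")
    return band_power(psd, band) / total


def theta_peak_frequency(psd: Psd, band: Tuple[float, float] = (4.0, 10.0)) -> float:
    """Frequency of maximum power in the theta band, refined by quadratic
    interpolation over the three bins around the argmax. Ties break toward
    the lower frequency; a flat in-band spectrum returns NaN."""
    m = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not m.any():
        raise ValueError("theta band not covered by PSD")
    f, p = psd.freqs[m], psd.power[m]
    if np.allclose(p, p[0]):
        import warnings
        warnings.warn("flat spectrum in theta band; peak undefined")
        return float("nan")
    i = int(np.argmax(p))
    if 0 < i < len(p) - 1:
        denom = p[i - 1] - 2 * p[i] + p[i + 1]
        if denom < 0:
            shift = 0.5 * (p[i - 1] - p[i + 1]) / denom
            return float(f[i] + shift * psd.df())
    return float(f[i])


# ----------------------------------------------------------------------
def theta_speed_correlation(lfp: np.ndarray, fs: float, speed: np.ndarray,
                            fs_speed: float, run_intervals: IntervalSet,
                            config: Optional[AnalysisConfig] = None,
                            window: float = 1.0) -> Tuple[float, float, int]:
    """Pearson correlation between theta-band power and mean running speed
    over non-overlapping windows (default 1 s) inside RUN intervals."""
    cfg = config or AnalysisConfig()
    if run_intervals.total_duration() < 60.0:
        raise ValueError("need >= 60 s of RUN for theta-speed correlation")
    seg = int(round(window * fs))
    starts = segment_starts(len(lfp), fs, seg, run_intervals)
    if len(starts) < 10:
        raise ValueError("fewer than 10 RUN windows")
    tapers = dpss_tapers(seg, cfg.mt_nw, cfg.mt_k)
    X = tapered_fft(_gather_segments(np.asarray(lfp, float), starts, seg), tapers)
    S = (np.abs(X) ** 2).mean(axis=1) / fs
    freqs = np.fft.rfftfreq(seg, 1.0 / fs)
    lo, hi = cfg.bands["theta"]
    theta = S[:, (freqs >= lo) & (freqs <= hi)].sum(axis=1) * (freqs[1] - freqs[0])
    # mean speed per window, on the speed-trace clock
    t0 = starts / fs
    sp = np.empty(len(starts))
    for j, t in enumerate(t0):
        a, b = int(round(t * fs_speed)), int(round((t + window) * fs_speed))
        sp[j] = np.mean(speed[a:max(b, a + 1)])
    if np.allclose(sp, sp[0]):
        raise ValueError("speed constant across windows; correlation undefined")
    r, p = sstats.pearsonr(theta, sp)
    return float(r), float(p), len(starts)


# ----------------------------------------------------------------------
def mt_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                 intervals: Optional[IntervalSet] = None,
                 config: Optional[AnalysisConfig] = None,
                 seg_len: Optional[float] = None,
                 nw: Optional[float] = None,
                 k: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Magnitude coherence |Sxy| / sqrt(Sxx Syy) with cross/auto spectra
    averaged over tapers and non-overlapping segments inside `intervals`."""
    cfg = config or AnalysisConfig()
    seg_len = seg_len or cfg.seg_len
    nw = nw or cfg.mt_nw
    k = k or cfg.mt_k
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("signals must share length and clock")
    seg = int(round(seg_len * fs))
    starts = segment_starts(len(x), fs, seg, intervals)
    if len(starts) == 0:
        raise ValueError("intervals shorter than one segment")
    tapers = dpss_tapers(seg, nw, k)
    X = tapered_fft(_gather_segments(x, starts, seg), tapers)
    Y = tapered_fft(_gather_segments(y, starts, seg), tapers)
    return np.fft.rfftfreq(seg, 1.0 / fs), coherence_from_ffts(X, Y)


def coherence_from_ffts(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Coherence from tapered segment FFTs of matching shape (S, K, F)."""
    Sxy = np.mean(X * np.conj(Y), axis=(0, 1))
    Sxx = np.mean(np.abs(X) ** 2, axis=(0, 1))
    Syy = np.mean(np.abs(Y) ** 2, axis=(0, 1))
    denom = np.sqrt(Sxx * Syy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sxy) / denom
    coh[~np.isfinite(coh)] = 0.0
    return np.clip(coh, 0.0, 1.0)
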