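"""Cross-frequency-coherence phase-amplitude coupling (PAC).

For each amplitude frequency fA the LFP is band-passed around fA, the
Hilbert envelope ("time-varying energy") is taken, and the multitaper
coherence spectrum between that envelope and the unfiltered raw signal is
evaluated at the phase frequencies. High coherence at (fP, fA) means the
fA-band amplitude waxes and wanes at the rhythm fP — for CA1 during
locomotion, the classic theta (6-8 Hz) phase x gamma (60-100 Hz) amplitude
region. Scalar quantification is the mean of the comodulogram over a fixed
a-priori region of high coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .containers import IntervalSet
from .filters import fft_bandpass
from .spectral import (coherence_from_ffts, dpss_tapers, tapered_fft,
                       _gather_segments)

__all__ = ["PacMatrix", "cfc_matrix", "pac_region_mean",
           "pac_region_surrogates", "amp_bandwidth"]


@dataclass
class PacMatrix:
    phase_freqs: np.ndarray     # Hz
    amp_freqs: np.ndarray       # Hz
    values: np.ndarray          # (n_amp, n_phase), coherence in [0, 1]
    seg_len: float
    nw: float
    k: int
    n_segments: int


def amp_bandwidth(fa: float) -> float:
    """Half-width of the amplitude band at fa: wide enough at high fa to
    pass theta-rate sidebands, narrow at low fa."""
    return max(2.0, fa / 8.0)


def _interval_segments(x, fs, intervals, seg):
    """Per-interval arrays and their segment start offsets (segments never
    straddle an interval boundary; filtering is per interval)."""
    if intervals is None or len(intervals) == 0:
        return [np.asarray(x, float)], [np.arange(0, len(x) - seg + 1, seg)]
    parts, starts = [], []
    for a, b, _ in intervals:
        i0, i1 = int(np.ceil(a * fs)), int(np.floor(b * fs))
        seg_count = (i1 - i0) // seg
        if seg_count < 1:
            continue
        parts.append(np.asarray(x[i0:i1], float))
        starts.append(seg * np.arange(seg_count))
    if not parts:
        raise ValueError("intervals shorter than one segment")
    return parts, starts


def _phase_grid(cfg: AnalysisConfig, phase_range):
    lo, hi = phase_range or cfg.pac_phase_range
    return np.arange(max(lo, cfg.pac_phase_step),
                     hi + 1e-9, cfg.pac_phase_step)


def _amp_grid(cfg: AnalysisConfig, amp_range):
    lo, hi = amp_range or cfg.pac_amp_range
    return np.arange(max(lo, cfg.pac_amp_step), hi + 1e-9, cfg.pac_amp_step)


def cfc_matrix(lfp: np.ndarray, fs: float,
               intervals: Optional[IntervalSet] = None,
               config: Optional[AnalysisConfig] = None,
               phase_range: Optional[Tuple[float, float]] = None,
               amp_range: Optional[Tuple[float, float]] = None,
               min_duration: float = 60.0) -> PacMatrix:
    """Comodulogram over the phase x amplitude frequency grids (defaults
    1-25 Hz x 1-300 Hz at 0.5 x 2 Hz resolution)."""
    cfg = config or AnalysisConfig()
    if intervals is not None and intervals.total_duration() < min_duration:
        raise ValueError(f"need >= {min_duration:g} s of the target state")
    seg = int(round(cfg.seg_len * fs))
    parts, starts_list = _interval_segments(lfp, fs, intervals, seg)
    tapers = dpss_tapers(seg, cfg.mt_nw, cfg.mt_k)

    raw_ffts = [tapered_fft(_gather_segments(part, st, seg), tapers)
                for part, st in zip(parts, starts_list)]
    Y = np.concatenate(raw_ffts, axis=0)

    freqs = np.fft.rfftfreq(seg, 1.0 / fs)
    phase_freqs = _phase_grid(cfg, phase_range)
    pcols = np.searchsorted(freqs, phase_freqs)
    if not np.allclose(freqs[pcols], phase_freqs, atol=1e-6):
        raise ValueError("phase grid must align with the segment FFT grid")

    amp_freqs = _amp_grid(cfg, amp_range)
    values = np.full((len(amp_freqs), len(phase_freqs)), np.nan)
    kept = np.ones(len(amp_freqs), dtype=bool)
    for r, fa in enumerate(amp_freqs):
        bw = amp_bandwidth(fa)
        lo, hi = max(fa - bw, 0.1), fa + bw
        if hi >= fs / 2:
            import warnings
            warnings.warn(f"amplitude band at {fa:g} Hz exceeds Nyquist; skipped")
            kept[r] = False
            continue
        env_ffts = []
        for part, st in zip(parts, starts_list):
            env = np.abs(sps.hilbert(fft_bandpass(part, fs, lo, hi)))
            env_ffts.append(tapered_fft(_gather_segments(env, st, seg), tapers))
        X = np.concatenate(env_ffts, axis=0)
        values[r] = coherence_from_ffts(X, Y)[pcols]
    return PacMatrix(phase_freqs=phase_freqs, amp_freqs=amp_freqs[kept],
                     values=values[kept], seg_len=cfg.seg_len,
                     nw=cfg.mt_nw, k=cfg.mt_k, n_segments=Y.shape[0])


def pac_region_mean(matrix: PacMatrix,
                    region: Tuple[Tuple[float, float], Tuple[float, float]]
                    ) -> float:
    """Mean comodulogram value over a closed (fP, fA) region."""
    (plo, phi), (alo, ahi) = region
    pm = (matrix.phase_freqs >= plo) & (matrix.phase_freqs <= phi)
    am = (matrix.amp_freqs >= alo) & (matrix.amp_freqs <= ahi)
    if not (pm.any() and am.any()):
        raise ValueError("region contains no comodulogram grid points")
    return float(np.nanmean(matrix.values[np.ix_(am, pm)]))


def pac_region_surrogates(lfp: np.ndarray, fs: float,
                          intervals: Optional[IntervalSet],
                          region, config: Optional[AnalysisConfig] = None,
                          n_surrogates: int = 100,
                          seed: int = 0) -> np.ndarray:
    """Phase-randomized null distribution of the PAC region mean.

    Each surrogate randomizes the Fourier phases of every amplitude-band
    envelope (magnitudes kept), destroying any envelope-phase coupling
    while preserving the envelope spectrum, then recomputes the region
    coherence against the unchanged raw signal.
    """
    cfg = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    (plo, phi), (alo, ahi) = region
    seg = int(round(cfg.seg_len * fs))
    parts, starts_list = _interval_segments(lfp, fs, intervals, seg)
    tapers = dpss_tapers(seg, cfg.mt_nw, cfg.mt_k)
    Y = np.concatenate([tapered_fft(_gather_segments(part, st, seg), tapers)
                        for part, st in zip(parts, starts_list)], axis=0)
    freqs = np.fft.rfftfreq(seg, 1.0 / fs)
    phase_freqs = _phase_grid(cfg, (plo, phi))
    pcols = np.searchsorted(freqs, phase_freqs)

    amp_freqs = _amp_grid(cfg, (alo, ahi))
    envs = []      # per amplitude row, per interval part
    for fa in amp_freqs:
        bw = amp_bandwidth(fa)
        row = [np.abs(sps.hilbert(fft_bandpass(part, fs, max(fa - bw, 0.1),
                                               fa + bw)))
               for part in parts]
        envs.append(row)

    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        vals = np.empty((len(amp_freqs), len(pcols)))
        for r, row in enumerate(envs):
            x_ffts = []
            for part_env, st in zip(row, starts_list):
                E = np.fft.rfft(part_env)
                phases = np.exp(1j * rng.uniform(0, 2 * np.pi, len(E)))
                phases[0] = 1.0
                surr = np.fft.irfft(E * phases, n=len(part_env))
                x_ffts.append(tapered_fft(_gather_segments(surr, st, seg),
                                          tapers))
            X = np.concatenate(x_ffts, axis=0)
            vals[r] = coherence_from_ffts(X, Y)[pcols]
        out[s] = vals.mean()
    return out
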