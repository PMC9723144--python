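"""Zero-phase filtering helpers shared across the pipeline."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import fft as sfft
from scipy import signal as sps


def fft_bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
                 transition: float | None = None) -> np.ndarray:
    """Zero-phase band-pass via frequency-domain masking with raised-cosine
    edges. `lo` may be 0 for a low-pass. Transition width defaults to
    min(1 Hz, band width / 4)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if hi >= fs / 2:
        raise ValueError("band edge at or above Nyquist")
    if transition is None:
        transition = max(min(1.0, (hi - lo) / 4.0), 0.05)
    nfft = sfft.next_fast_len(n)
    freqs = sfft.rfftfreq(nfft, 1.0 / fs)
    gain = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    gain[inside] = 1.0
    # cosine roll-offs on both shoulders
    if lo > 0:
        ramp = (freqs >= lo - transition) & (freqs < lo)
        gain[ramp] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[ramp]) / transition))
    upper = (freqs > hi) & (freqs <= hi + transition)
    gain[upper] = 0.5 * (1 + np.cos(np.pi * (freqs[upper] - hi) / transition))
    return sfft.irfft(sfft.rfft(x, n=nfft) * gain, n=nfft)[:n]


@lru_cache(maxsize=32)
def _blackman_fir(fs: float, lo: float, hi: float, taps_per_cycle: float,
                  max_taps: int) -> np.ndarray:
    numtaps = int(min(max_taps, round(taps_per_cycle * fs / lo)))
    numtaps |= 1  # odd length -> exactly symmetric, integer group delay
    return sps.firwin(numtaps, [lo, hi], pass_zero=False,
                      window="blackman", fs=fs)


def blackman_bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
                      taps_per_cycle: float = 4.0,
                      max_taps: int = 8192) -> np.ndarray:
    """Zero-phase Blackman-windowed FIR band-pass.

    The symmetric (linear-phase) FIR is applied by centered convolution,
    which cancels the group delay exactly — a single pass is zero-phase.
    """
    if hi >= fs / 2:
        raise ValueError("band edge at or above Nyquist")
    h = _blackman_fir(float(fs), float(lo), float(hi),
                      float(taps_per_cycle), int(max_taps))
    return sps.fftconvolve(np.asarray(x, dtype=float), h, mode="same")


def envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope), computed at a
    fast FFT length and truncated back."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nfft = sfft.next_fast_len(n)
    return np.abs(sps.hilbert(x, N=nfft)[:n])


def moving_average(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Centered moving average preserving length (edge replication)."""
    from scipy.ndimage import uniform_filter1d
    width_samples = max(1, int(width_samples))
    return uniform_filter1d(np.asarray(x, dtype=float), size=width_samples,
                            mode="nearest")
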