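"""Coherence between single-cell calcium traces and the LFP.

The LFP is first downsampled to the 20 Hz calcium frame rate (zero-phase
anti-alias low-pass, then decimation), so the coherence spectrum lives on
[0, 10] Hz; the scalar summary is the maximum coherence in the theta band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .containers import IntervalSet
from .filters import fft_bandpass
from .spectral import mt_coherence

__all__ = ["CoherenceSpectrum", "downsample_lfp", "trace_lfp_coherence",
           "theta_coherence_peak"]


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    coherence: np.ndarray      # in [0, 1]
    n_segments: int


def downsample_lfp(lfp: np.ndarray, fs_in: float, fs_out: float = 20.0
                   ) -> np.ndarray:
    """Zero-phase low-pass at 0.4*fs_out followed by decimation.

    fs_in must be an integer multiple of fs_out; output length is
    ceil(n * fs_out / fs_in).
    """
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fs_in must be an integer multiple of fs_out")
    ratio = int(round(ratio))
    if ratio == 1:
        return np.asarray(lfp, dtype=float).copy()
    cutoff = 0.4 * fs_out
    low = fft_bandpass(lfp, fs_in, 0.0, cutoff, transition=0.15 * fs_out)
    return low[::ratio]


def trace_lfp_coherence(trace: np.ndarray, lfp20: np.ndarray, fs: float = 20.0,
                        intervals: Optional[IntervalSet] = None,
                        config: Optional[AnalysisConfig] = None
                        ) -> Optional[CoherenceSpectrum]:
    """Multitaper coherence between one DeltaF/F trace and the downsampled
    LFP over 2 s segments inside the given state intervals."""
    cfg = config or AnalysisConfig()
    if intervals is not None and intervals.total_duration() < 60.0:
        raise ValueError("need >= 60 s of the target state")
    trace = np.asarray(trace, dtype=float)
    if trace.std() == 0:
        warnings.warn("zero-variance trace: coherence undefined")
        return None
    freqs, coh = mt_coherence(trace, lfp20, fs, intervals=intervals, config=cfg)
    n_seg = max(1, int((intervals.total_duration() if intervals is not None
                        else len(trace) / fs) // cfg.seg_len))
    return CoherenceSpectrum(freqs=freqs, coherence=coh, n_segments=n_seg)


def theta_coherence_peak(spec: CoherenceSpectrum,
                         config: Optional[AnalysisConfig] = None) -> float:
    """Maximum coherence in the theta band (4-10 Hz)."""
    cfg = config or AnalysisConfig()
    lo, hi = cfg.bands["theta"]
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not m.any():
        raise ValueError("theta band not covered by coherence spectrum")
    return float(np.max(spec.coherence[m]))
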