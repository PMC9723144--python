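"""Behavioral state segmentation: RUN, QW, SWS, REM.

Rules (speed from position, band ratios from the s. radiatum LFP):
  RUN  - running on the track, speed > 3 cm/s;
  QW   - wakeful immobility (< 0.5 cm/s) lasting > 10 s;
  SWS  - immobility with delta/theta power ratio > 2 sustained >= 3 min;
  REM  - theta/delta power ratio > 2 for >= 30 s arising out of SWS.

Samples meeting no rule stay unlabeled. Priority on ties:
REM > SWS > QW > RUN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import binary_closing

from .config import AnalysisConfig
from .containers import IntervalSet
from .filters import moving_average
from .spectral import dpss_tapers, _gather_segments

__all__ = ["SpeedTrace", "BandRatioTrace", "compute_speed",
           "band_ratio_trace", "classify_states"]


@dataclass
class SpeedTrace:
    values: np.ndarray      # cm/s, non-negative, same length as position
    fs: float
    smoothing: str = ""


@dataclass
class BandRatioTrace:
    times: np.ndarray       # window centers, s
    delta_theta: np.ndarray
    theta_delta: np.ndarray
    window: float = 2.0
    step: float = 0.25


def compute_speed(position: np.ndarray, fs: float,
                  smooth: float = 0.5) -> SpeedTrace:
    """|dx| * fs smoothed by a centered moving average (default 0.5 s); the
    first sample is duplicated to preserve length."""
    position = np.asarray(position, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if len(position) < 2:
        raise ValueError("need >= 2 position samples")
    raw = np.abs(np.diff(position)) * fs
    raw = np.r_[raw[0], raw]
    sm = moving_average(raw, int(round(smooth * fs)))
    return SpeedTrace(values=sm, fs=fs,
                      smoothing=f"moving_average({smooth:g}s)")


def band_ratio_trace(lfp: np.ndarray, fs: float,
                     config: Optional[AnalysisConfig] = None,
                     window: Optional[float] = None,
                     step: Optional[float] = None,
                     chunk: int = 1024) -> BandRatioTrace:
    """Delta/theta (and inverse) multitaper band-power ratios over sliding
    windows (default 2 s window, 0.25 s step for classification)."""
    cfg = config or AnalysisConfig()
    window = window or cfg.ratio_window
    step = step or cfg.ratio_step
    lfp = np.asarray(lfp, dtype=float)
    if not np.any(lfp):
        raise ValueError("degenerate LFP: all-zero signal")
    win = int(round(window * fs))
    hop = max(1, int(round(step * fs)))
    if len(lfp) < win:
        raise ValueError("LFP shorter than one ratio window")
    starts = np.arange(0, len(lfp) - win + 1, hop)
    tapers = dpss_tapers(win, cfg.mt_nw, cfg.mt_k)
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    dlo, dhi = cfg.bands["delta"]
    tlo, thi = cfg.bands["theta"]
    # half-open at the shared 4 Hz edge so no bin is counted twice
    dmask = (freqs >= dlo) & (freqs < min(dhi, tlo))
    tmask = (freqs >= tlo) & (freqs <= thi)
    keep = dmask | tmask
    # only the low-frequency DFT bins are needed: evaluate them directly
    # as a matrix product instead of a full FFT per window
    F = np.exp(-2j * np.pi * freqs[keep][:, None]
               * (np.arange(win) / fs)[None, :])      # (n_bins, win)
    dsel = dmask[keep]
    tsel = tmask[keep]
    k = tapers.shape[0]
    delta = np.empty(len(starts))
    theta = np.empty(len(starts))
    for i in range(0, len(starts), chunk):
        segs = _gather_segments(lfp, starts[i:i + chunk], win)
        segs = segs - segs.mean(axis=1, keepdims=True)
        tap = (segs[:, None, :] * tapers[None, :, :]).reshape(-1, win)
        X = tap @ F.T                                  # (S*k, n_bins)
        S = (np.abs(X) ** 2).reshape(len(segs), k, -1).mean(axis=1)
        delta[i:i + chunk] = S[:, dsel].sum(axis=1)
        theta[i:i + chunk] = S[:, tsel].sum(axis=1)
    eps = 1e-300
    dt = (delta + eps) / (theta + eps)
    return BandRatioTrace(times=(starts + win / 2.0) / fs, delta_theta=dt,
                          theta_delta=1.0 / dt, window=window, step=step)


# ----------------------------------------------------------------------
def _runs(mask: np.ndarray):
    """(start, end) index pairs of True runs."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask.any() and mask[-1]:
        ends = np.r_[ends, len(mask)]
    return list(zip(starts.tolist(), ends.tolist()))


def _close(mask: np.ndarray, width: int) -> np.ndarray:
    """Morphological closing with edge replication so runs touching the
    record boundary are not eroded."""
    if width <= 1 or not mask.any():
        return mask
    pad = width
    padded = np.r_[np.repeat(mask[0], pad), mask, np.repeat(mask[-1], pad)]
    closed = binary_closing(padded, structure=np.ones(width, dtype=bool))
    return closed[pad:-pad]


def classify_states(speed: SpeedTrace, ratios: BandRatioTrace,
                    config: Optional[AnalysisConfig] = None) -> IntervalSet:
    """Segment the session into RUN/QW/SWS/REM intervals on the calcium
    frame grid.

    SWS epochs are delimited by per-window delta/theta > 2 within immobility
    (the >= 3 min minimum applies to the epoch); REM requires theta/delta > 2
    for >= 30 s starting within 60 s of the end of an SWS interval. Sustained
    high-theta epochs without a preceding SWS interval stay unlabeled.
    """
    cfg = config or AnalysisConfig()
    fs = speed.fs
    n = len(speed.values)
    t = np.arange(n) / fs
    dt_ratio = np.interp(t, ratios.times, ratios.delta_theta)
    td_ratio = np.interp(t, ratios.times, ratios.theta_delta)

    close_w = int(round(cfg.state_closing * fs))
    immobile = _close(speed.values < cfg.qw_speed_max, close_w)
    running = _close(speed.values > cfg.run_speed_min, close_w)

    # running median makes the ratio regimes flicker-free while keeping
    # regime transitions sharp (the ratio jumps by an order of magnitude
    # between sleep stages)
    from scipy.ndimage import median_filter
    med_w = max(1, int(round(cfg.ratio_median_window * fs)))
    dt_med = median_filter(dt_ratio, size=med_w, mode="nearest")
    td_med = median_filter(td_ratio, size=med_w, mode="nearest")
    sws_like = immobile & (dt_med > cfg.sws_delta_theta_ratio)
    rem_like = immobile & (td_med > cfg.rem_theta_delta_ratio)

    min_f = lambda dur: int(np.ceil(dur * fs))
    labels = np.full(n, None, dtype=object)

    # SWS: qualifying sws_like runs (REM-like frames carved out first so a
    # following REM epoch does not dilute or extend the SWS run)
    sws_runs = [r for r in _runs(sws_like & ~rem_like)
                if r[1] - r[0] >= min_f(cfg.sws_immobility_min)]
    for a, b in sws_runs:
        if np.median(dt_ratio[a:b]) > cfg.sws_delta_theta_ratio:
            labels[a:b] = "SWS"

    # REM: long high-theta immobility arising out of SWS (gap <= rem_max_gap)
    sws_ends = np.array([b for a, b in _runs(labels == "SWS")], dtype=float)
    rem_candidates = [
        r for r in _runs(rem_like)
        if r[1] - r[0] >= min_f(cfg.rem_min_dur)
        and np.median(td_ratio[r[0]:r[1]]) > cfg.rem_theta_delta_ratio]
    for a, b in rem_candidates:
        gap_ok = sws_ends.size and np.any(
            (sws_ends <= a) & (a - sws_ends <= cfg.rem_max_gap * fs))
        if gap_ok:
            sel = slice(a, b)
            labels[sel] = np.where(labels[sel] == None, "REM", labels[sel])  # noqa: E711
        # else: unlabeled — high-theta epoch not arising out of SWS
        else:
            immobile[a:b] = False   # exclude from QW as well

    # QW: leftover immobility runs > 10 s
    free_immobile = immobile & (labels == None)  # noqa: E711
    for a, b in _runs(free_immobile):
        if b - a > min_f(cfg.qw_min_dur):
            labels[a:b] = "QW"

    # RUN: remaining fast samples
    free_run = running & (labels == None)  # noqa: E711
    for a, b in _runs(free_run):
        labels[a:b] = "RUN"

    parts = []
    for state in ("RUN", "QW", "SWS", "REM"):
        m = labels == state
        if m.any():
            parts.append(IntervalSet.from_mask(m, fs, state))
    return IntervalSet.concat(parts)
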