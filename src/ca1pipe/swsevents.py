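"""Slow-wave-sleep event analysis: SWR and spindle detection, SWR-spindle
PETHs, event-triggered band power, and SWR-triggered calcium modulation.

Detection follows the Hilbert-envelope convention: band-pass (zero-phase
Blackman FIR), envelope, Z-score against all SWS samples, and keep maximal
supra-threshold runs longer than the band's minimum duration (spindles:
1.25 Z / 200 ms on the cortical channel; ripples: 3 Z / 20 ms on the
pyramidal-layer channel). Event onset is the first threshold crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .containers import EventTimes, IntervalSet
from .filters import blackman_bandpass, envelope

__all__ = ["DetectedEvent", "Peth", "detect_band_events", "detect_swr",
           "detect_spindles", "swr_spindle_peth", "event_triggered_band_power",
           "event_triggered_calcium", "swr_calcium_modulation"]


@dataclass
class Peth:
    edges: np.ndarray       # bin edges, s relative to trigger
    rate: np.ndarray        # events/s per trigger
    counts: np.ndarray
    n_triggers: int


def _runs_of(mask: np.ndarray):
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask.any() and mask[-1]:
        ends = np.r_[ends, len(mask)]
    return starts, ends


def detect_band_events(lfp: np.ndarray, fs: float, band: Tuple[float, float],
                       z_thr: float, min_dur: float, sws: IntervalSet,
                       config: Optional[AnalysisConfig] = None,
                       label: str = "event") -> pd.DataFrame:
    """Envelope-threshold detection inside SWS intervals.

    Returns a DataFrame (label, onset, offset, peak_z, peak_time). Events
    separated by less than `event_merge_gap` are merged; the duration rule
    is exact — no emitted event is shorter than `min_dur`.
    """
    cfg = config or AnalysisConfig()
    if band[1] >= fs / 2:
        raise ValueError("band above Nyquist")
    if sws.total_duration() < 10.0:
        raise ValueError("need >= 10 s of SWS for envelope statistics")
    x = np.asarray(lfp, dtype=float)
    filt = blackman_bandpass(x, fs, band[0], band[1],
                             cfg.fir_taps_per_cycle, cfg.fir_max_taps)
    env = envelope(filt)
    if cfg.env_smooth > 0:
        from scipy.ndimage import gaussian_filter1d
        env = gaussian_filter1d(env, sigma=cfg.env_smooth * fs)
    t = np.arange(len(x)) / fs
    sws_mask = sws.contains(t)
    mu, sd = env[sws_mask].mean(), env[sws_mask].std()
    if sd == 0:
        raise ValueError("degenerate envelope (zero variance in SWS)")
    z = (env - mu) / sd

    above = (z > z_thr) & sws_mask
    starts, ends = _runs_of(above)
    if len(starts) == 0:
        return pd.DataFrame(columns=["label", "onset", "offset", "peak_z",
                                     "peak_time"])
    # supra-threshold runs separated by less than the merge gap belong to
    # one event; the duration rule applies to the event's total time above
    # threshold, so chatter never adds up to an event and interference dips
    # never split one
    gap = cfg.event_merge_gap * fs
    clusters = [[starts[0], ends[0], ends[0] - starts[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - clusters[-1][1] <= gap:
            clusters[-1][2] += e - s
            clusters[-1][1] = e
        else:
            clusters.append([s, e, e - s])
    min_samples = int(np.ceil(min_dur * fs))
    rows = []
    for s, e, supra in clusters:
        if supra < min_samples:
            continue
        peak = s + int(np.argmax(z[s:e]))
        rows.append((label, s / fs, e / fs, float(z[peak]), peak / fs))
    return pd.DataFrame(rows, columns=["label", "onset", "offset", "peak_z",
                                       "peak_time"])


def detect_swr(pcl_lfp: np.ndarray, fs: float, sws: IntervalSet,
               config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    cfg = config or AnalysisConfig()
    return detect_band_events(pcl_lfp, fs, cfg.bands["ripple"], cfg.swr_z,
                              cfg.swr_min_dur, sws, cfg, label="SWR")


def detect_spindles(cortex_lfp: np.ndarray, fs: float, sws: IntervalSet,
                    config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    cfg = config or AnalysisConfig()
    return detect_band_events(cortex_lfp, fs, cfg.bands["spindle"],
                              cfg.spindle_z, cfg.spindle_min_dur, sws, cfg,
                              label="spindle")


# ----------------------------------------------------------------------
def swr_spindle_peth(swr_onsets: np.ndarray, spindle_onsets: np.ndarray,
                     config: Optional[AnalysisConfig] = None) -> Peth:
    """Histogram of SWR onsets around spindle onsets (default [-1, 1] s,
    30 ms bins), as SWR rate per second per trigger."""
    cfg = config or AnalysisConfig()
    spindle_onsets = np.asarray(spindle_onsets, dtype=float)
    swr_onsets = np.asarray(swr_onsets, dtype=float)
    if len(spindle_onsets) < 5:
        raise ValueError("need >= 5 spindle triggers for a PETH")
    lo, hi = cfg.peth_window
    n_bins = int(round((hi - lo) / cfg.peth_bin))
    edges = lo + cfg.peth_bin * np.arange(n_bins + 1)
    rel = (swr_onsets[None, :] - spindle_onsets[:, None]).ravel()
    counts, _ = np.histogram(rel, bins=edges)
    rate = counts / (len(spindle_onsets) * cfg.peth_bin)
    return Peth(edges=edges, rate=rate, counts=counts,
                n_triggers=len(spindle_onsets))


# ----------------------------------------------------------------------
def event_triggered_band_power(lfp: np.ndarray, fs: float,
                               onsets: np.ndarray, band: Tuple[float, float],
                               config: Optional[AnalysisConfig] = None,
                               rng: Optional[np.random.Generator] = None
                               ) -> dict:
    """Band envelope power around event onsets on a 1 ms grid.

    Returns the across-event mean power trace over `trig_power_window`
    ([-2, +2] s) plus per-event "at" (mean power in [-0.25, +0.25] s) and
    matched "outside" values (0.5 s windows centered >= 1 s from any event).
    """
    cfg = config or AnalysisConfig()
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) < 10:
        raise ValueError("need >= 10 event onsets")
    rng = rng or np.random.default_rng(cfg.seed)
    filt = blackman_bandpass(lfp, fs, band[0], band[1],
                             cfg.fir_taps_per_cycle, cfg.fir_max_taps)
    power = envelope(filt) ** 2
    # 1 ms grid
    per_bin = max(1, int(round(cfg.power_bin * fs)))
    n_bins_total = len(power) // per_bin
    p1ms = power[:n_bins_total * per_bin].reshape(n_bins_total, per_bin).mean(axis=1)
    fs_grid = fs / per_bin

    lo, hi = cfg.trig_power_window
    pre_bins = int(round(-lo * fs_grid))
    post_bins = int(round(hi * fs_grid))
    traces = []
    for t0 in onsets:
        c = int(round(t0 * fs_grid))
        if c - pre_bins < 0 or c + post_bins > len(p1ms):
            warnings.warn("event-triggered window truncated at record edge")
            continue
        traces.append(p1ms[c - pre_bins:c + post_bins])
    traces = np.asarray(traces)
    times = (np.arange(-pre_bins, post_bins) + 0.5) / fs_grid

    at_lo, at_hi = cfg.at_window
    at_mask = (times >= at_lo) & (times <= at_hi)
    at_vals = traces[:, at_mask].mean(axis=1)

    # matched control windows centered >= outside_min_gap from any event
    half = (at_hi - at_lo) / 2.0
    t_total = len(p1ms) / fs_grid
    out_vals = []
    tries = 0
    while len(out_vals) < len(at_vals) and tries < 200 * len(at_vals):
        tries += 1
        c = rng.uniform(half + abs(lo), t_total - half - abs(hi))
        if np.min(np.abs(onsets - c)) < cfg.outside_min_gap:
            continue
        i0 = int(round((c - half) * fs_grid))
        i1 = int(round((c + half) * fs_grid))
        out_vals.append(p1ms[i0:i1].mean())
    return {
        "times": times,
        "mean_power": traces.mean(axis=0),
        "at": at_vals,
        "outside": np.asarray(out_vals),
        "n_events": len(at_vals),
    }


def event_triggered_calcium(ca_traces: np.ndarray, fs_ca: float,
                            onsets: np.ndarray,
                            config: Optional[AnalysisConfig] = None) -> dict:
    """Per-cell DeltaF/F averaged over windows around event onsets on the
    `ca_trig_bin` (50 ms) grid; population mean +/- SEM included."""
    cfg = config or AnalysisConfig()
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) < 10:
        raise ValueError("need >= 10 event onsets")
    lo, hi = cfg.ca_trig_window
    step = cfg.ca_trig_bin
    frames_per_bin = max(1, int(round(step * fs_ca)))
    pre = int(round(-lo / step))
    post = int(round(hi / step))
    n_cells, n_frames = ca_traces.shape
    windows = []
    for t0 in onsets:
        c = int(round(t0 * fs_ca))
        a = c - pre * frames_per_bin
        b = c + post * frames_per_bin
        if a < 0 or b > n_frames:
            warnings.warn("calcium-triggered window truncated at record edge")
            continue
        w = ca_traces[:, a:b].reshape(n_cells, pre + post, frames_per_bin)
        windows.append(w.mean(axis=2))
    stack = np.asarray(windows)                   # (events, cells, bins)
    mean_matrix = stack.mean(axis=0)              # cells x bins
    pop_mean = mean_matrix.mean(axis=0)
    pop_sem = mean_matrix.std(axis=0, ddof=1) / np.sqrt(n_cells)
    times = (np.arange(-pre, post) + 0.5) * step
    return {"times": times, "cell_mean": mean_matrix, "pop_mean": pop_mean,
            "pop_sem": pop_sem, "n_events": len(windows)}


# ----------------------------------------------------------------------
def _merged_windows(onsets: np.ndarray, rel: Tuple[float, float],
                    t_max: float) -> IntervalSet:
    iv = sorted((max(t0 + rel[0], 0.0), min(t0 + rel[1], t_max))
                for t0 in onsets)
    merged = []
    for a, b in iv:
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return IntervalSet.from_tuples([(a, b, "w") for a, b in merged])


def swr_calcium_modulation(events: EventTimes, onsets: np.ndarray,
                           session_duration: float,
                           config: Optional[AnalysisConfig] = None
                           ) -> Tuple[float, float, float]:
    """Pooled calcium event rate (transients/min per cell) in the pre
    ([-5, -2] s), at ([-0.25, +0.25] s) and post ([+1, +2] s) windows around
    SWR onsets. Overlapping windows of the same class are merged so no time
    is double counted."""
    cfg = config or AnalysisConfig()
    onsets = np.asarray(onsets, dtype=float)
    if len(onsets) < 10:
        raise ValueError("need >= 10 SWR onsets")
    n_cells = max(events.n_cells, 1)
    out = []
    for rel in (cfg.pre_window, cfg.at_window, cfg.post_window):
        win = _merged_windows(onsets, rel, session_duration)
        total_min = win.total_duration() / 60.0
        count = int(win.contains(events.df["onset"].to_numpy()).sum())
        out.append(count / (total_min * n_cells) if total_min > 0 else np.nan)
    return tuple(out)
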