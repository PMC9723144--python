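"""Calcium transient detection, per-state event rates, and hypo-/hyperactive
cell classification.

An event is a supra-threshold excursion of the z-scored DeltaF/F trace
(2 Z above the full-session mean). The onset is the time the trace last rose
through 30% of that event's peak before the peak, located by linear
interpolation between frames. Rates are transients/min per behavioral state;
hypoactive cells fire < 0.25 transients/min, hyperactive cells exceed the
reference population mean by more than 2 SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .containers import EventTimes, IntervalSet, STATES

__all__ = ["detect_calcium_events", "detect_events_matrix",
           "event_rates_by_state", "classify_activity", "ActivityClass"]


def _supra_runs(z: np.ndarray, thr: float):
    above = z > thr
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(z)]
    return list(zip(starts.tolist(), ends.tolist()))


def _onset_time(z: np.ndarray, peak_idx: int, peak_z: float, frac: float,
                fs: float) -> float:
    """Last upward crossing of frac*peak before the peak, sub-frame by
    linear interpolation; falls back to the trace start if never below."""
    thr = frac * peak_z
    i = peak_idx
    while i > 0 and z[i - 1] > thr:
        i -= 1
    if i == 0:
        return 0.0
    # z[i-1] <= thr < z[i]
    frac_step = (thr - z[i - 1]) / (z[i] - z[i - 1])
    return ((i - 1) + frac_step) / fs


def detect_calcium_events(trace: np.ndarray, fs: float,
                          config: Optional[AnalysisConfig] = None,
                          cell: int = 0) -> pd.DataFrame:
    """Detect events in one DeltaF/F trace.

    Returns a DataFrame (cell, onset, peak_time, peak_z). The trace is
    z-scored against its own full-session mean/SD; events are maximal runs
    above `ca_event_z` lasting at least `ca_min_dur`; events with peaks
    closer than `ca_min_sep` are merged (larger peak kept).
    """
    cfg = config or AnalysisConfig()
    x = np.asarray(trace, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("trace shorter than 2 s")
    sd = x.std()
    if sd == 0:
        warnings.warn("zero-variance trace: no events")
        return pd.DataFrame({c: [] for c in EventTimes.COLUMNS})
    z = (x - x.mean()) / sd

    min_samples = max(1, int(round(cfg.ca_min_dur * fs)))
    runs = [(a, b) for a, b in _supra_runs(z, cfg.ca_event_z)
            if b - a >= min_samples]

    # hysteresis: a run is a continuation of the previous event unless the
    # trace returned below the release level in between (suppresses
    # re-crossings on the decaying transient tail)
    groups: list[list[int]] = []
    for a, b in runs:
        if groups and z[groups[-1][1]:a].min() > cfg.ca_release_z:
            groups[-1][1] = b
        else:
            groups.append([a, b])

    # confirmation on a smoothed copy (indicator-timescale boxcar) rejects
    # isolated noise doublets; timing/amplitude stay on the raw trace
    if cfg.ca_confirm_smooth > 0:
        from scipy.ndimage import uniform_filter1d
        w = max(1, int(round(cfg.ca_confirm_smooth * fs)))
        xs = uniform_filter1d(x, w, mode="nearest")
        xs_sd = xs.std()
        if xs_sd > 0:
            zs = (xs - xs.mean()) / xs_sd
            groups = [g for g in groups if zs[g[0]:g[1]].max() > cfg.ca_event_z]

    peaks = [a + int(np.argmax(z[a:b])) for a, b in groups]

    # merge peaks closer than ca_min_sep, keeping the larger; idempotent
    min_sep = cfg.ca_min_sep * fs
    merged: list[int] = []
    for p in peaks:
        if merged and (p - merged[-1]) < min_sep:
            if z[p] > z[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)

    rows = []
    for p in merged:
        pz = float(z[p])
        rows.append((cell, _onset_time(z, p, pz, cfg.ca_onset_frac, fs),
                     p / fs, pz))
    return pd.DataFrame(rows, columns=list(EventTimes.COLUMNS))


def detect_events_matrix(ca_traces: np.ndarray, fs: float,
                         config: Optional[AnalysisConfig] = None) -> EventTimes:
    """Run the detector over every cell of a (cells x frames) matrix."""
    frames = []
    for i in range(ca_traces.shape[0]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frames.append(detect_calcium_events(ca_traces[i], fs, config, cell=i))
    frames = [f for f in frames if len(f)]
    df = pd.concat(frames, ignore_index=True) if frames else None
    return EventTimes(df, n_cells=ca_traces.shape[0])


# ----------------------------------------------------------------------
def event_rates_by_state(events: EventTimes, states: IntervalSet,
                         config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Rate table: cells x states, transients/min.

    A state observed for less than `min_state_dur_for_rate` (30 s) yields a
    missing value for every cell.
    """
    cfg = config or AnalysisConfig()
    if len(states) == 0:
        raise ValueError("empty state segmentation")
    labels = [s for s in STATES if (states.labels == s).any()]
    out = pd.DataFrame(index=pd.RangeIndex(events.n_cells, name="cell"),
                       columns=labels, dtype=float)
    for state in labels:
        iv = states.select(state)
        minutes = iv.total_duration() / 60.0
        if minutes * 60.0 < cfg.min_state_dur_for_rate:
            out[state] = np.nan
            continue
        inside = iv.contains(events.df["onset"].to_numpy())
        counts = np.zeros(events.n_cells)
        cells = events.df["cell"].to_numpy()[inside]
        np.add.at(counts, cells, 1)
        out[state] = counts / minutes
    return out


def animal_mean_rates(rates: pd.DataFrame) -> pd.Series:
    """Animal-level summary: mean rate over cells per state."""
    return rates.mean(axis=0, skipna=True)


# ----------------------------------------------------------------------
@dataclass
class ActivityClass:
    labels: pd.DataFrame        # cells x states, {hypoactive, normal, hyperactive}
    reference_mean: pd.Series   # per state
    reference_sd: pd.Series
    proportions: pd.DataFrame   # states x labels, fraction of cells


def classify_activity(rates: pd.DataFrame, reference: pd.DataFrame,
                      config: Optional[AnalysisConfig] = None) -> ActivityClass:
    """Label each cell per state as hypoactive / normal / hyperactive.

    The hyperactivity threshold is mean + 2 SD of the reference population
    (cells pooled across reference animals, per state). Hypoactivity
    (< 0.25 transients/min) takes precedence when both hold.
    """
    cfg = config or AnalysisConfig()
    for state in rates.columns:
        ref = reference.get(state)
        if ref is None:
            raise ValueError(f"state {state} absent from reference rates")
        if ref.dropna().shape[0] < 2:
            raise ValueError(f"reference needs >= 2 cells for state {state}")
    mean = reference.mean(axis=0, skipna=True)
    sd = reference.std(axis=0, ddof=1)
    labels = pd.DataFrame("normal", index=rates.index, columns=rates.columns)
    for state in rates.columns:
        r = rates[state]
        hyper = r > mean[state] + cfg.hyper_sd * sd[state]
        hypo = r < cfg.hypo_rate
        labels.loc[hyper, state] = "hyperactive"
        labels.loc[hypo, state] = "hypoactive"   # precedence over hyper
        labels.loc[r.isna(), state] = "missing"
    props = pd.DataFrame(
        {state: labels[state].value_counts(normalize=True)
         for state in rates.columns}).T.fillna(0.0)
    return ActivityClass(labels=labels, reference_mean=mean,
                         reference_sd=sd, proportions=props)
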