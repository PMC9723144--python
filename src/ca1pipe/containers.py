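"""Core data containers: sessions, interval sets, event times, test results.

Time convention: everything lives on the session clock in seconds, intervals
are half-open [start, end); calcium frame k covers [k/fs_ca, (k+1)/fs_ca).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

LFP_ROLES = ("pcl", "srad", "cortex")
STATES = ("RUN", "QW", "SWS", "REM")


# ----------------------------------------------------------------------
class IntervalSet:
    """Sorted, non-overlapping labeled intervals [start, end) in seconds."""

    def __init__(self, starts=(), ends=(), labels=()):
        self.starts = np.asarray(starts, dtype=float)
        self.ends = np.asarray(ends, dtype=float)
        self.labels = np.asarray(labels, dtype=object)
        if not (len(self.starts) == len(self.ends) == len(self.labels)):
            raise ValueError("starts, ends, labels must have equal length")
        order = np.argsort(self.starts, kind="stable")
        self.starts, self.ends, self.labels = (
            self.starts[order], self.ends[order], self.labels[order])
        if np.any(self.ends <= self.starts):
            raise ValueError("every interval needs end > start")
        if len(self.starts) > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("intervals overlap")

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "IntervalSet":
        tuples = list(tuples)
        if not tuples:
            return cls()
        s, e, l = zip(*tuples)
        return cls(s, e, l)

    def __len__(self):
        return len(self.starts)

    def __iter__(self):
        return iter(zip(self.starts, self.ends, self.labels))

    def __repr__(self):
        return f"IntervalSet({len(self)} intervals, labels={sorted(set(self.labels))})"

    def select(self, label: str) -> "IntervalSet":
        m = self.labels == label
        return IntervalSet(self.starts[m], self.ends[m], self.labels[m])

    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    def total_duration(self, label: Optional[str] = None) -> float:
        iv = self if label is None else self.select(label)
        return float(np.sum(iv.durations()))

    def contains(self, times) -> np.ndarray:
        """Boolean mask: which of `times` fall inside any interval."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.starts, times, side="right") - 1
        ok = idx >= 0
        out = np.zeros(times.shape, dtype=bool)
        out[ok] = times[ok] < self.ends[idx[ok]]
        return out

    def label_at(self, times) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.starts, times, side="right") - 1
        out = np.full(times.shape, None, dtype=object)
        ok = (idx >= 0)
        inside = np.zeros_like(ok)
        inside[ok] = times[ok] < self.ends[idx[ok]]
        out[inside] = self.labels[idx[inside]]
        return out

    @classmethod
    def from_mask(cls, mask: np.ndarray, fs: float, label: str,
                  t0: float = 0.0) -> "IntervalSet":
        """Convert a boolean sample mask into intervals (sample k covers
        [k/fs, (k+1)/fs))."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            return cls()
        d = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, len(mask)]
        return cls(t0 + starts / fs, t0 + ends / fs, [label] * len(starts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.starts, "end": self.ends,
                             "label": self.labels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        return cls(df["start"].to_numpy(), df["end"].to_numpy(),
                   df["label"].to_numpy())

    @staticmethod
    def concat(parts: Sequence["IntervalSet"]) -> "IntervalSet":
        if not parts:
            return IntervalSet()
        return IntervalSet(
            np.concatenate([p.starts for p in parts]),
            np.concatenate([p.ends for p in parts]),
            np.concatenate([p.labels for p in parts]))


# ----------------------------------------------------------------------
class EventTimes:
    """Per-cell calcium event onsets with peak amplitude (Z) and peak time.

    Backed by a DataFrame with columns (cell, onset, peak_time, peak_z);
    onsets are strictly increasing within a cell.
    """

    COLUMNS = ("cell", "onset", "peak_time", "peak_z")

    def __init__(self, df: Optional[pd.DataFrame] = None, n_cells: Optional[int] = None):
        if df is None:
            df = pd.DataFrame({c: [] for c in self.COLUMNS})
        df = df.copy()
        df["cell"] = df["cell"].astype(int)
        df = df.sort_values(["cell", "onset"], kind="stable").reset_index(drop=True)
        for cell, grp in df.groupby("cell"):
            on = grp["onset"].to_numpy()
            if np.any(np.diff(on) <= 0):
                raise ValueError(f"cell {cell}: onsets must be strictly increasing")
        self.df = df
        self.n_cells = int(n_cells) if n_cells is not None else (
            int(df["cell"].max()) + 1 if len(df) else 0)

    def __len__(self):
        return len(self.df)

    def cell(self, i: int) -> pd.DataFrame:
        return self.df[self.df["cell"] == i]

    def onsets(self, i: Optional[int] = None) -> np.ndarray:
        sel = self.df if i is None else self.cell(i)
        return sel["onset"].to_numpy()

    def counts_per_cell(self) -> np.ndarray:
        out = np.zeros(self.n_cells, dtype=int)
        vc = self.df["cell"].value_counts()
        out[vc.index.to_numpy()] = vc.to_numpy()
        return out

    @classmethod
    def from_records(cls, records, n_cells=None) -> "EventTimes":
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        return cls(df, n_cells=n_cells)


# ----------------------------------------------------------------------
@dataclass
class Session:
    """One recording session on a common clock.

    lfp channels sampled at fs_lfp; ca_traces (cells x frames) and position
    at fs_ca; position in cm along a linear track.
    """

    lfp: dict
    ca_traces: np.ndarray
    position: np.ndarray
    track_length: float
    fs_lfp: float = 2000.0
    fs_ca: float = 20.0
    meta: dict = field(default_factory=dict)
    emg: Optional[np.ndarray] = None
    ground_truth: Optional[object] = None

    @property
    def n_cells(self) -> int:
        return self.ca_traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.ca_traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fs_ca

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs_ca

    def validate(self) -> "Session":
        missing = [r for r in LFP_ROLES if r not in self.lfp]
        if missing:
            raise ValueError(f"channel role {missing[0]} absent")
        lengths = {len(np.asarray(v)) for v in self.lfp.values()}
        if len(lengths) != 1:
            raise ValueError("LFP channels differ in length")
        if self.ca_traces.ndim != 2:
            raise ValueError("ca_traces must be cells x frames")
        if len(self.position) != self.n_frames:
            raise ValueError("position and ca_traces frame counts differ")
        n_lfp = lengths.pop()
        expected = self.n_frames * self.fs_lfp / self.fs_ca
        if abs(n_lfp - expected) > self.fs_lfp / self.fs_ca:
            raise ValueError("LFP and calcium stream durations differ by > 1 frame")
        for role, x in self.lfp.items():
            if np.isnan(x).any():
                raise ValueError(f"NaNs in LFP channel {role}")
        if np.isnan(self.ca_traces).any():
            raise ValueError("NaNs in ca_traces")
        if np.isnan(self.position).any():
            raise ValueError("NaNs in position")
        if self.position.min() < -1e-9 or self.position.max() > self.track_length + 1e-9:
            raise ValueError("position outside [0, track_length]")
        return self


# ----------------------------------------------------------------------
@dataclass
class GroupResult:
    """Outcome of one statistical test, with optional post-hoc list."""

    test_name: str
    statistic: float
    df: tuple
    p_value: float
    post_hoc: Optional[list] = None    # list of (comparison, p) tuples
    effect_summary: Optional[dict] = None  # group -> (mean, sem)
    notes: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
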