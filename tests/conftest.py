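import numpy as np
import pytest
from hypothesis import settings

from ca1pipe.config import AnalysisConfig
from ca1pipe.containers import IntervalSet

settings.register_profile("ca1pipe", database=None, deadline=None,
                          derandomize=True)
settings.load_profile("ca1pipe")


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig().validate()


@pytest.fixture(scope="session")
def small_session():
    """One short four-state synthetic session shared across read-only tests."""
    from ca1pipe import synth

    p = synth.SimParams(
        schedule=[("RUN", 120.0), ("QW", 60.0), ("SWS", 200.0), ("REM", 40.0)],
        n_cells=12)
    return synth.generate_session(p, seed=42)


def ca_kernel(fs: float, rise: float = 0.07, decay: float = 0.5) -> np.ndarray:
    t = np.arange(0, 3.0, 1.0 / fs)
    k = (1 - np.exp(-t / rise)) * np.exp(-t / decay)
    return k / k.max()


def greedy_match(detected: np.ndarray, truth: np.ndarray, tol: float):
    """One-to-one greedy matching by time distance; returns matched count."""
    pairs = sorted((abs(d - t), i, j)
                   for i, t in enumerate(truth)
                   for j, d in enumerate(detected) if abs(d - t) < tol)
    ui, uj = set(), set()
    for _, i, j in pairs:
        if i not in ui and j not in uj:
            ui.add(i)
            uj.add(j)
    return len(ui)


def interval_recovery(det_on, det_off, truth: IntervalSet):
    """Recall/precision/onset-error for detections against true intervals
    (a detection overlapping a true interval counts for that interval)."""
    det_on = np.asarray(det_on)
    det_off = np.asarray(det_off)
    matched = np.zeros(len(det_on), dtype=bool)
    tp, errs = 0, []
    for a, b, _ in truth:
        ov = (det_on < b) & (det_off > a)
        if ov.any():
            tp += 1
            matched[ov] = True
            errs.append(abs(det_on[np.flatnonzero(ov)[0]] - a))
    recall = tp / len(truth) if len(truth) else np.nan
    precision = matched.sum() / len(det_on) if len(det_on) else np.nan
    return recall, precision, (np.median(errs) if errs else np.nan)
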