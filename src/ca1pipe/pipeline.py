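"""End-to-end session analysis and cohort contrasts.

`analyze_session` runs the full chain on one session: state segmentation,
calcium event detection and rates, PAC region mean in RUN, and SWR-triggered
calcium modulation in SWS. `compare_cohorts` turns two lists of session
results into the headline group comparisons: QW event-rate deficit
(two-sample t), RUN hyperactive-proportion excess (chi-square on pooled
cells), and PAC reduction (two-sample t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calcium, pac, states, swsevents
from .config import AnalysisConfig
from .containers import IntervalSet, Session

__all__ = ["SessionResult", "analyze_session", "compare_cohorts"]


@dataclass
class SessionResult:
    animal_id: str
    states: IntervalSet
    rates: pd.DataFrame                    # cells x states, transients/min
    mean_rates: pd.Series                  # per state, mean over cells
    pac_region_mean: float
    modulation: Optional[tuple]            # (pre, at, post) or None
    n_cells: int
    extras: dict = field(default_factory=dict)


def analyze_session(session: Session,
                    config: Optional[AnalysisConfig] = None,
                    run_pac: bool = True,
                    run_modulation: bool = True) -> SessionResult:
    cfg = config or AnalysisConfig()
    speed = states.compute_speed(session.position, session.fs_ca,
                                 cfg.speed_smooth)
    ratios = states.band_ratio_trace(session.lfp["srad"], session.fs_lfp, cfg)
    seg = states.classify_states(speed, ratios, cfg)

    events = calcium.detect_events_matrix(session.ca_traces, session.fs_ca, cfg)
    rates = calcium.event_rates_by_state(events, seg, cfg)

    pac_mean = np.nan
    if run_pac:
        run_iv = seg.select("RUN")
        if run_iv.total_duration() >= 60.0:
            matrix = pac.cfc_matrix(
                session.lfp["srad"], session.fs_lfp, run_iv, cfg,
                phase_range=cfg.pac_region_default[0],
                amp_range=cfg.pac_region_default[1])
            pac_mean = pac.pac_region_mean(matrix, cfg.pac_region_default)

    modulation = None
    if run_modulation:
        sws_iv = seg.select("SWS")
        if sws_iv.total_duration() >= 10.0:
            swr = swsevents.detect_swr(session.lfp["pcl"], session.fs_lfp,
                                       sws_iv, cfg)
            if len(swr) >= 10:
                modulation = swsevents.swr_calcium_modulation(
                    events, swr["onset"].to_numpy(), session.duration, cfg)

    return SessionResult(
        animal_id=str(session.meta.get("animal_id", "?")),
        states=seg, rates=rates, mean_rates=rates.mean(axis=0, skipna=True),
        pac_region_mean=pac_mean, modulation=modulation,
        n_cells=session.n_cells, extras={"events": events})


# ----------------------------------------------------------------------
def _pooled_hyper_counts(results: Sequence[SessionResult],
                         reference: pd.DataFrame, state: str,
                         cfg: AnalysisConfig) -> tuple:
    """(n_hyperactive, n_other) pooling cells across the cohort's animals."""
    hyper = other = 0
    for r in results:
        if state not in r.rates.columns:
            continue
        cls = calcium.classify_activity(r.rates[[state]], reference[[state]], cfg)
        counts = cls.labels[state].value_counts()
        hyper += int(counts.get("hyperactive", 0))
        other += int(sum(counts.get(k, 0) for k in ("normal", "hypoactive")))
    return hyper, other


def compare_cohorts(control: Sequence[SessionResult],
                    test: Sequence[SessionResult],
                    config: Optional[AnalysisConfig] = None) -> dict:
    """Headline group contrasts between a control and a test cohort."""
    from . import stats as gs

    cfg = config or AnalysisConfig()
    out = {}

    qw_c = [r.mean_rates.get("QW", np.nan) for r in control]
    qw_t = [r.mean_rates.get("QW", np.nan) for r in test]
    qw_c = [v for v in qw_c if np.isfinite(v)]
    qw_t = [v for v in qw_t if np.isfinite(v)]
    out["qw_rate"] = gs.two_sample_test(qw_c, qw_t)

    reference = pd.concat([r.rates for r in control], ignore_index=True)
    c_hyper = _pooled_hyper_counts(control, reference, "RUN", cfg)
    t_hyper = _pooled_hyper_counts(test, reference, "RUN", cfg)
    out["run_hyper"] = gs.proportion_chi2([list(c_hyper), list(t_hyper)])
    out["run_hyper_fracs"] = (c_hyper[0] / max(sum(c_hyper), 1),
                              t_hyper[0] / max(sum(t_hyper), 1))

    pac_c = [r.pac_region_mean for r in control if np.isfinite(r.pac_region_mean)]
    pac_t = [r.pac_region_mean for r in test if np.isfinite(r.pac_region_mean)]
    out["pac"] = gs.two_sample_test(pac_c, pac_t)

    for name, cohort in (("control", control), ("test", test)):
        trip = [r.modulation for r in cohort if r.modulation is not None]
        if len(trip) >= 3:
            table = pd.DataFrame(trip, columns=["pre", "at", "post"])
            out[f"modulation_{name}"] = gs.rm_anova_states(table)
    return out
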