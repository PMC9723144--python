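"""Generator correctness: determinism, injected statistics, ground truth."""

import numpy as np
import pytest

from ca1pipe import spectral, states, synth


def test_bit_reproducible():
    a, _ = synth.generate_session(synth.SimParams(
        schedule=[("RUN", 60.0), ("SWS", 120.0)], n_cells=4), seed=3)
    b, _ = synth.generate_session(synth.SimParams(
        schedule=[("RUN", 60.0), ("SWS", 120.0)], n_cells=4), seed=3)
    np.testing.assert_array_equal(a.position, b.position)
    for role in a.lfp:
        np.testing.assert_array_equal(a.lfp[role], b.lfp[role])
    np.testing.assert_array_equal(a.ca_traces, b.ca_traces)
    c, _ = synth.generate_session(synth.SimParams(
        schedule=[("RUN", 60.0), ("SWS", 120.0)], n_cells=4), seed=4)
    assert not np.array_equal(a.ca_traces, c.ca_traces)


def test_run_behavior_laps_and_speed():
    p = synth.SimParams(schedule=[("RUN", 600.0)])
    ses, truth = synth.generate_session(p, seed=0)
    speed = states.compute_speed(ses.position, ses.fs_ca)
    distance = np.abs(np.diff(ses.position)).sum()
    assert distance / (2 * p.track_length) >= 10      # >= 10 full laps
    assert np.mean(speed.values > 3.0) > 0.99


def test_immobile_states_stay_still():
    p = synth.SimParams(schedule=[("QW", 60.0), ("SWS", 200.0)])
    ses, _ = synth.generate_session(p, seed=1)
    speed = states.compute_speed(ses.position, ses.fs_ca)
    assert speed.values.max() < 0.5


def test_swr_count_poisson(cfg):
    p = synth.SimParams(schedule=[("SWS", 600.0)],
                        swr_rate={"SWS": 6.0}, swr_so_coupling=False)
    _, truth = synth.generate_session(p, seed=5)
    lam = 60.0
    assert abs(len(truth.swr) - lam) < 4 * np.sqrt(lam)


def test_calcium_count_poisson():
    p = synth.SimParams(schedule=[("RUN", 600.0)], n_cells=1, place_frac=0.0,
                        hypo_frac=0.0, hyper_frac=0.0, rate_spread_sigma=0.0,
                        ca_rates={"RUN": 2.0, "QW": 0, "SWS": 0, "REM": 0},
                        ca_theta_lock=0.0, swr_ca_dip=0.0)
    _, truth = synth.generate_session(p, seed=6)
    lam = 20.0
    assert abs(len(truth.events) - lam) < 4 * np.sqrt(lam)


def test_dip_minus_one_silences_dip_windows():
    p = synth.SimParams(schedule=[("SWS", 400.0)], swr_ca_dip=-1.0,
                        n_cells=6, hypo_frac=0, hyper_frac=0,
                        ca_rates={"RUN": 0, "QW": 0, "SWS": 6.0, "REM": 0})
    _, truth = synth.generate_session(p, seed=7)
    ev = truth.events.df["onset"].to_numpy()
    for onset in truth.swr.starts:
        inside = (ev >= onset - 0.5) & (ev < onset + 0.5)
        assert not inside.any()


def test_injected_oscillations_peak_in_band(cfg):
    ses, _ = synth.generate_session(
        synth.SimParams(schedule=[("RUN", 120.0)]), seed=2)
    psd = spectral.multitaper_psd(ses.lfp["srad"], ses.fs_lfp, config=cfg)
    theta = (psd.freqs >= 4) & (psd.freqs <= 10)
    assert psd.freqs[theta][np.argmax(psd.power[theta])] == pytest.approx(7.0, abs=1.0)
    ses2, _ = synth.generate_session(
        synth.SimParams(schedule=[("SWS", 120.0)]), seed=2)
    # 8 s segments: +/- NW/T smearing stays below 0.4 Hz around the SO line
    psd2 = spectral.multitaper_psd(ses2.lfp["cortex"], ses2.fs_lfp,
                                   seg_len=8.0, config=cfg)
    so = (psd2.freqs >= 0.5) & (psd2.freqs <= 1.0)
    other = (psd2.freqs >= 2.0) & (psd2.freqs <= 10.0)
    assert psd2.power[so].max() > 10 * psd2.power[other].max()


def test_all_signals_finite(small_session):
    ses, _ = small_session
    assert np.isfinite(ses.ca_traces).all()
    assert all(np.isfinite(x).all() for x in ses.lfp.values())
    assert np.isfinite(ses.position).all()


def test_swr_spindle_coupling_lag():
    p = synth.SimParams(schedule=[("SWS", 600.0)], swr_spindle_coupling=1.0,
                        spindle_rate=4.0, swr_rate={"SWS": 4.0},
                        swr_so_coupling=False)
    _, truth = synth.generate_session(p, seed=9)
    lags = []
    for sp in truth.spindles.starts:
        d = truth.swr.starts - sp
        close = d[np.abs(d) < 0.3]
        if len(close):
            lags.append(close[0])
    assert len(lags) >= 0.5 * len(truth.spindles)
    assert np.median(lags) == pytest.approx(-0.1, abs=0.02)


def test_preset_cohort_directions():
    ctrl = synth.preset_params("control-like")
    app = synth.preset_params("APP-like")
    assert app.ca_rates["QW"] < ctrl.ca_rates["QW"]
    assert app.hyper_frac > ctrl.hyper_frac
    assert app.hypo_frac > ctrl.hypo_frac
    assert app.pac_depth < ctrl.pac_depth
    assert app.so_amp < ctrl.so_amp
    assert app.swr_spindle_coupling < ctrl.swr_spindle_coupling
    assert app.swr_ca_dip == 0.0 and ctrl.swr_ca_dip < 0
    assert app.theta_speed_slope < ctrl.theta_speed_slope
    with pytest.raises(ValueError, match="unknown"):
        synth.preset_params("other")


def test_preset_cohort_shared_schedule():
    ctrl = synth.preset_cohort("control-like", 2, seed=1)
    app = synth.preset_cohort("APP-like", 2, seed=1)
    for (s1, t1), (s2, t2) in zip(ctrl, app):
        assert t1.params.schedule == t2.params.schedule
        np.testing.assert_array_equal(t1.states.starts, t2.states.starts)
        assert s1.meta["genotype"] != s2.meta["genotype"]


def test_param_validation():
    with pytest.raises(ValueError):
        synth.SimParams(pac_depth=1.5).validate()
    with pytest.raises(ValueError):
        synth.SimParams(schedule=[("RUN", -5.0)]).validate()
    with pytest.raises(ValueError):
        synth.SimParams(ca_decay=0.0).validate()
    with pytest.raises(ValueError):
        synth.SimParams(hypo_frac=0.5, hyper_frac=0.4,
                        place_frac=0.3).validate()


def test_session_passes_load_validation(small_session):
    ses, truth = small_session
    ses.validate()
    assert set(ses.lfp) == {"pcl", "srad", "cortex"}
    assert truth.states.total_duration() == pytest.approx(ses.duration)
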