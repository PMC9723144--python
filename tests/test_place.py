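"""Spatial tuning curves, Skaggs information, and the shuffle test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ca1pipe import place, states, synth
from ca1pipe.place import TuningCurve, spatial_information


def _curve(occ, counts):
    occ = np.asarray(occ, float)
    counts = np.asarray(counts, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ >= 0.5, counts / occ, np.nan)
    return TuningCurve("rightward", np.arange(len(occ)), occ, counts, rate)


class TestSpatialInformation:
    def test_flat_curve_zero(self):
        assert spatial_information(_curve(np.ones(10), np.ones(10))) == 0.0

    def test_one_of_four_bins_two_bits(self):
        si = spatial_information(_curve(np.ones(4), [8, 0, 0, 0]))
        assert si == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            nb = int(rng.integers(4, 50))
            occ = rng.uniform(0.5, 5.0, nb)
            counts = rng.poisson(2.0, nb).astype(float)
            tc = _curve(occ, counts)
            si = spatial_information(tc)
            p = occ / occ.sum()
            lam = counts / occ
            lam_bar = float((p * lam).sum())
            oracle = sum(pi * (li / lam_bar) * np.log2(li / lam_bar)
                         for pi, li in zip(p, lam) if li > 0)
            assert si == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_invariant_under_rate_scaling(self, c):
        occ = np.array([1.0, 2.0, 0.7, 3.0])
        counts = np.array([3.0, 0.0, 5.0, 1.0])
        a = spatial_information(_curve(occ, counts))
        b = spatial_information(_curve(occ, c * counts))
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_rate_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(spatial_information(_curve(np.ones(5), np.zeros(5))))


class TestTuningCurve:
    def test_events_land_in_their_bins(self, cfg):
        fs, track = 20.0, 200.0
        n = int(600 * fs)
        rng = np.random.default_rng(0)
        position = np.abs(((np.arange(n) / fs * 15.0) % (2 * track)) - track)
        mask = np.ones(n, dtype=bool)
        ev_frames = rng.choice(np.flatnonzero((position > 90) & (position < 110)),
                               40, replace=False)
        tc = place.spatial_tuning_curve(np.sort(ev_frames) / fs, position,
                                        mask, fs, track, config=cfg)
        nz = np.flatnonzero(np.nan_to_num(tc.rate) > 0)
        assert tc.centers[nz].min() >= 87.0 and tc.centers[nz].max() <= 113.0

    def test_direction_masks_partition_run(self, cfg):
        p = synth.SimParams(schedule=[("RUN", 200.0)])
        ses, _ = synth.generate_session(p, seed=0)
        sp = states.compute_speed(ses.position, ses.fs_ca)
        masks = place.direction_masks(ses.position, sp.values, ses.fs_ca, cfg)
        both = masks["rightward"] & masks["leftward"]
        assert not both.any()
        union = masks["rightward"] | masks["leftward"]
        assert np.array_equal(union, sp.values > cfg.run_speed_min)


class TestPlaceCellTest:
    @pytest.fixture(scope="class")
    def run_session(self):
        # well-sampled cells (~50 events per direction, no rate spread):
        # isolates the test's power for the default field shape
        p = synth.SimParams(schedule=[("RUN", 600.0)], n_cells=60,
                            place_frac=0.5, hypo_frac=0.0, hyper_frac=0.0,
                            rate_spread_sigma=0.0,
                            ca_rates={"RUN": 8.0, "QW": 1, "SWS": 1, "REM": 1},
                            ca_refractory=0.15, swr_ca_dip=0.0)
        return synth.generate_session(p, seed=2)

    def test_same_seed_identical_p(self, cfg, run_session):
        ses, truth = run_session
        sp = states.compute_speed(ses.position, ses.fs_ca)
        cell = int(np.flatnonzero(np.isfinite(truth.place_fields))[0])
        ev = truth.events.onsets(cell)
        r1 = place.place_cell_test(ev, ses.position, sp.values, ses.fs_ca,
                                   ses.track_length, cfg, seed=7, n_shuffles=100)
        r2 = place.place_cell_test(ev, ses.position, sp.values, ses.fs_ca,
                                   ses.track_length, cfg, seed=7, n_shuffles=100)
        for d in place.DIRECTIONS:
            assert r1[d]["p"] == r2[d]["p"]

    def test_recovers_generator_fields(self, cfg, run_session):
        ses, truth = run_session
        sp = states.compute_speed(ses.position, ses.fs_ca)
        is_pc = np.isfinite(truth.place_fields)
        hits = 0
        peak_errors = []
        for cell in np.flatnonzero(is_pc):
            r = place.place_cell_test(truth.events.onsets(cell), ses.position,
                                      sp.values, ses.fs_ca, ses.track_length,
                                      cfg, seed=50 + cell, n_shuffles=300)
            if r["is_place_cell"]:
                hits += 1
                best = min((r[d] for d in place.DIRECTIONS),
                           key=lambda x: np.inf if np.isnan(x["p"]) else x["p"])
                curve = best["curve"]
                peak = curve.centers[np.nanargmax(np.nan_to_num(curve.rate))]
                peak_errors.append(abs(peak - truth.place_fields[cell]))
        assert hits / is_pc.sum() >= 0.85
        # typical field localization within two spatial bins
        assert np.median(peak_errors) <= 6.0

    def test_too_few_events_flagged_not_error(self, cfg, run_session):
        ses, _ = run_session
        sp = states.compute_speed(ses.position, ses.fs_ca)
        r = place.place_cell_test(np.array([10.0, 20.0]), ses.position,
                                  sp.values, ses.fs_ca, ses.track_length,
                                  cfg, seed=1, n_shuffles=50)
        assert not r["is_place_cell"]
        assert any(r[d]["flag"] == "too_few_events" for d in place.DIRECTIONS)
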