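"""Synthetic session generator with recorded ground truth.

Emulates the statistical structure the analysis assumes: a RUN/QW/SWS/REM
state schedule on a 200 cm linear track; s. radiatum theta with
speed-dependent amplitude and gamma amplitude-coupled to theta phase with a
controllable depth m; SWS with pyramidal-layer sharp-wave ripples, cortical
spindles and a slow oscillation with controllable SWR-spindle and SWR-SO
coordination; and DeltaF/F calcium traces built from kernel-convolved
inhomogeneous Poisson events with state-dependent rates, hypo-/hyperactive
subpopulations, Gaussian place fields and an optional SWR-locked rate dip.

Every generated array is a deterministic function of (params, seed), and the
generator returns the injected truth (state schedule, event intervals,
event times, place-field map) for parameter-recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .containers import EventTimes, IntervalSet, Session
from .filters import envelope, fft_bandpass

__all__ = ["SimParams", "GroundTruth", "generate_behavior", "generate_lfp",
           "generate_calcium", "generate_session", "preset_params",
           "preset_cohort", "pink_noise", "burst_train"]


def default_schedule() -> List[Tuple[str, float]]:
    return [("RUN", 360.0), ("QW", 180.0), ("SWS", 360.0), ("REM", 90.0)]


@dataclass
class SimParams:
    """Generator parameters. Rates are events/min, durations s, amplitudes
    in the arbitrary LFP units of the 1/f background (SD `noise_sd`)."""

    schedule: List[Tuple[str, float]] = field(default_factory=default_schedule)
    fs_lfp: float = 2000.0
    fs_ca: float = 20.0
    track_length: float = 200.0

    # behavior
    run_speed_mean: float = 15.0     # cm/s
    run_speed_var: float = 7.0       # sinusoidal speed modulation amplitude

    # oscillations
    theta_freq: float = 7.0
    # per-state oscillation amplitudes are set so each state satisfies its
    # defining delta/theta ratio with margin on top of the 1/f background
    # (which alone carries more delta- than theta-band power)
    theta_amp: dict = field(default_factory=lambda: {
        "RUN": 2.0, "QW": 0.8, "SWS": 0.2, "REM": 2.5})
    theta_speed_slope: float = 0.10  # amplitude per cm/s, RUN only
    delta_amp: dict = field(default_factory=lambda: {
        "RUN": 0.3, "QW": 0.48, "SWS": 2.5, "REM": 0.15})
    gamma_center: float = 80.0
    gamma_bw: float = 20.0
    gamma_amp: float = 0.8
    pac_depth: float = 0.8           # m in [0, 1]

    # SWS events
    so_freq: float = 0.75
    so_amp: float = 2.5
    so_mod_freq: float = 0.04        # slow amplitude modulation of the SO
    so_mod_depth: float = 0.6
    spindle_rate: float = 3.0
    spindle_dur: float = 0.5
    spindle_freq: float = 14.0
    spindle_snr: float = 8.0         # peak envelope / in-band background SD
    swr_rate: dict = field(default_factory=lambda: {"QW": 3.0, "SWS": 8.0})
    swr_dur: float = 0.05
    swr_freq: float = 140.0
    swr_snr: float = 5.0
    swr_spindle_lag: float = -0.1    # SWR onset relative to spindle onset
    swr_spindle_coupling: float = 0.7
    swr_so_coupling: bool = True
    burst_taper: float = 0.2         # Tukey taper fraction of burst packets
    event_min_sep: float = 0.25

    # background noise
    noise_alpha: float = 1.0
    noise_sd: float = 1.0

    # calcium
    n_cells: int = 60
    ca_rates: dict = field(default_factory=lambda: {
        "RUN": 1.5, "QW": 0.9, "SWS": 0.7, "REM": 0.6})
    rate_spread_sigma: float = 0.4   # lognormal cell-to-cell spread
    hypo_frac: float = 0.08
    hypo_cell_rate: float = 0.1
    hyper_frac: float = 0.02
    hyper_cell_rate: float = 5.0
    place_frac: float = 0.3
    field_width: float = 12.0        # Gaussian SD, cm
    field_gain: float = 6.0          # peak in-field rate multiplier
    ca_rise: float = 0.07
    ca_decay: float = 0.5
    ca_amp_z: float = 5.0            # transient amplitude / trace noise SD
    ca_amp_jitter: float = 0.1       # lognormal sigma on amplitudes
    ca_noise_sd: float = 0.2         # DeltaF/F white noise SD
    ca_theta_lock: float = 0.2       # event-rate modulation by theta phase
    ca_theta_trace_amp: float = 0.5  # theta-band DeltaF/F SD / noise SD
    ca_refractory: float = 0.3
    swr_ca_dip: float = -0.4         # fractional rate change near SWR onsets
    dip_window: Tuple[float, float] = (-0.5, 0.5)

    seed: int = 0

    def validate(self) -> "SimParams":
        if not self.schedule or any(d <= 0 for _, d in self.schedule):
            raise ValueError("schedule durations must be > 0")
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth m must be in [0, 1]")
        for d in (self.ca_rates, self.swr_rate):
            if any(v < 0 for v in d.values()):
                raise ValueError("rates must be >= 0")
        if self.hypo_frac + self.hyper_frac + self.place_frac > 1.0 + 1e-9:
            raise ValueError("cell-class fractions sum above 1")
        if self.ca_decay <= 0:
            raise ValueError("calcium kernel decay must be > 0")
        return self

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.schedule))

    def state_intervals(self) -> IntervalSet:
        t, rows = 0.0, []
        for label, dur in self.schedule:
            rows.append((t, t + dur, label))
            t += dur
        return IntervalSet.from_tuples(rows)


@dataclass
class GroundTruth:
    states: IntervalSet
    swr: IntervalSet
    spindles: IntervalSet
    events: EventTimes
    place_fields: np.ndarray      # per-cell field center (cm); NaN = non-place
    cell_class: np.ndarray        # 'normal' | 'hypoactive' | 'hyperactive'
    params: SimParams


# ----------------------------------------------------------------------
def pink_noise(n: int, alpha: float, sd: float, rng: np.random.Generator,
               fs: float = 1.0) -> np.ndarray:
    """Gaussian 1/f^alpha noise, standardized to the requested SD."""
    from scipy import fft as sfft

    nfft = sfft.next_fast_len(n)
    white = rng.standard_normal(nfft)
    X = sfft.rfft(white)
    f = sfft.rfftfreq(nfft, 1.0 / fs)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2.0)
    shaping[0] = 0.0
    x = sfft.irfft(X * shaping, n=nfft)[:n]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def burst_train(n: int, fs: float, onsets: np.ndarray, dur: float, freq: float,
                amp: float, taper: float, rng: np.random.Generator
                ) -> Tuple[np.ndarray, IntervalSet]:
    """Sum of flat-top (Tukey-windowed) sinusoid packets with random initial
    phase; returns the signal and the true [onset, offset) intervals."""
    x = np.zeros(n)
    L = int(round(dur * fs))
    win = sps.windows.tukey(L, alpha=taper)
    rows = []
    for t0 in np.sort(np.asarray(onsets, dtype=float)):
        i0 = int(round(t0 * fs))
        if i0 < 0 or i0 + L > n:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(L) / fs
        x[i0:i0 + L] += amp * win * np.sin(2 * np.pi * freq * tt + phase)
        rows.append((i0 / fs, (i0 + L) / fs, "burst"))
    return x, IntervalSet.from_tuples(rows)


def _poisson_onsets(rng: np.random.Generator, intervals: IntervalSet,
                    rate_per_min: float, dur: float, min_sep: float,
                    weight=None) -> np.ndarray:
    """Poisson event onsets inside intervals, kept `min_sep` apart and fully
    inside their interval; optional acceptance weight w(t) in [0, 1]."""
    out = []
    for a, b, _ in intervals:
        if b - a <= dur:
            continue
        n_target = rng.poisson(rate_per_min * (b - a) / 60.0)
        picked: list[float] = []
        attempts = 0
        while len(picked) < n_target and attempts < 50 * max(n_target, 1):
            attempts += 1
            t = rng.uniform(a, b - dur)
            if weight is not None and rng.uniform() > weight(t):
                continue
            if all(abs(t - q) >= min_sep + dur for q in picked):
                picked.append(t)
        out.extend(picked)
    return np.sort(np.asarray(out))


# ----------------------------------------------------------------------
def generate_behavior(params: SimParams, rng: np.random.Generator
                      ) -> Tuple[np.ndarray, IntervalSet]:
    """Position trace (cm at fs_ca) for the schedule: back-and-forth
    traversals during RUN, sub-threshold jitter elsewhere."""
    p = params
    if p.track_length <= 2 * AnalysisConfig().spatial_bin:
        raise ValueError("track_length too short for spatial binning")
    fs = p.fs_ca
    pieces = []
    pos0 = p.track_length / 2.0
    direction = 1.0
    for label, dur in p.schedule:
        n = int(round(dur * fs))
        if label == "RUN":
            t = np.arange(n) / fs
            speed = p.run_speed_mean + p.run_speed_var * np.sin(
                2 * np.pi * t / 60.0 + rng.uniform(0, 2 * np.pi))
            steps = direction * speed / fs
            x = pos0 + np.cumsum(steps)
            # reflect at the track ends
            period = 2 * p.track_length
            x = np.mod(x, period)
            x = np.where(x > p.track_length, period - x, x)
            pos0 = x[-1]
            direction = 1.0 if x[-1] < p.track_length / 2 else -1.0
        else:
            jitter = np.clip(np.cumsum(rng.normal(0.0, 0.002, n)), -0.4, 0.4)
            x = np.clip(pos0 + jitter, 0.0, p.track_length)
            pos0 = x[-1]
        pieces.append(x)
    return np.concatenate(pieces), params.state_intervals()


# ----------------------------------------------------------------------
def _gaussian_band_noise(white: np.ndarray, fs: float, center: float,
                         fwhm: float) -> np.ndarray:
    """Noise with a Gaussian spectral profile (no sharp band edges)."""
    from scipy import fft as sfft

    n = len(white)
    nfft = sfft.next_fast_len(n)
    f = sfft.rfftfreq(nfft, 1.0 / fs)
    sigma = fwhm / 2.355
    shaping = np.exp(-0.5 * ((f - center) / sigma) ** 2)
    return sfft.irfft(sfft.rfft(white, n=nfft) * shaping, n=nfft)[:n]


def generate_lfp(params: SimParams, position: np.ndarray,
                 rng: np.random.Generator
                 ) -> Tuple[dict, IntervalSet, IntervalSet]:
    """Three LFP channels plus the true SWR and spindle interval sets."""
    p = params
    fs = p.fs_lfp
    n = int(round(p.duration * fs))
    if p.gamma_center + p.gamma_bw / 2 >= fs / 2 or p.swr_freq >= fs / 2:
        raise ValueError("oscillation band collides with Nyquist")
    t = np.arange(n) / fs
    states = p.state_intervals()

    def state_mask(*labs):
        m = np.zeros(n, dtype=bool)
        for a, b, lab in states:
            if lab in labs:
                m[int(round(a * fs)):int(round(b * fs))] = True
        return m

    # per-sample theta amplitude (a0 per state, + slope * speed in RUN)
    amp = np.zeros(n)
    for lab, a0 in p.theta_amp.items():
        amp[state_mask(lab)] = a0
    frame_speed = np.abs(np.r_[0.0, np.diff(position)]) * p.fs_ca
    speed_lfp = np.interp(t, np.arange(len(position)) / p.fs_ca, frame_speed)
    run_mask = state_mask("RUN")
    amp[run_mask] += p.theta_speed_slope * speed_lfp[run_mask]

    theta_phase = 2 * np.pi * p.theta_freq * t + rng.uniform(0, 2 * np.pi)
    theta = amp * np.sin(theta_phase)

    # carrier kept below 3 Hz so multitaper smearing (±NW/T) cannot push
    # delta power into the 4-10 Hz theta estimate
    delta_carrier = fft_bandpass(rng.standard_normal(n), fs, 0.5, 3.0)
    delta_carrier /= delta_carrier.std()
    delta = np.zeros(n)
    for lab, a0 in p.delta_amp.items():
        delta[state_mask(lab)] = a0
    delta = delta * delta_carrier

    carrier = _gaussian_band_noise(rng.standard_normal(n), fs,
                                   p.gamma_center, p.gamma_bw)
    carrier /= envelope(carrier).mean()
    gamma_gate = state_mask("RUN", "REM").astype(float)
    gamma = (p.gamma_amp * gamma_gate *
             (1.0 + p.pac_depth * np.cos(theta_phase)) * carrier)

    srad = theta + delta + gamma + pink_noise(n, p.noise_alpha, p.noise_sd, rng, fs)

    # --- cortex: slow oscillation + spindles ------------------------------
    cortex_noise = pink_noise(n, p.noise_alpha, p.noise_sd, rng, fs)
    so_mod_phase = rng.uniform(0, 2 * np.pi)
    so_mod = 1.0 + p.so_mod_depth * np.sin(2 * np.pi * p.so_mod_freq * t
                                           + so_mod_phase)
    sws_gate = state_mask("SWS").astype(float)
    so = p.so_amp * so_mod * sws_gate * np.sin(
        2 * np.pi * p.so_freq * t + rng.uniform(0, 2 * np.pi))

    sws_iv = states.select("SWS")
    sp_sigma = fft_bandpass(cortex_noise, fs, 12.0, 16.0).std()
    spindle_onsets = _poisson_onsets(rng, sws_iv, p.spindle_rate,
                                     p.spindle_dur, p.event_min_sep)
    spindle_sig, spindle_iv = burst_train(
        n, fs, spindle_onsets, p.spindle_dur, p.spindle_freq,
        p.spindle_snr * sp_sigma, p.burst_taper, rng)
    cortex = cortex_noise + so + spindle_sig

    # --- pyramidal layer: SWR bursts --------------------------------------
    pcl_noise = pink_noise(n, p.noise_alpha, p.noise_sd, rng, fs)
    swr_sigma = fft_bandpass(pcl_noise, fs, 100.0, 300.0).std()
    weight = None
    if p.swr_so_coupling and p.so_mod_depth > 0:
        wmin, wspan = 1.0 - p.so_mod_depth, 2.0 * p.so_mod_depth
        weight = lambda tt: (1.0 + p.so_mod_depth * np.sin(
            2 * np.pi * p.so_mod_freq * tt + so_mod_phase) - wmin) / wspan  # noqa: E731
    swr_onsets = []
    for lab, rate in p.swr_rate.items():
        iv = states.select(lab)
        if len(iv) == 0 or rate <= 0:
            continue
        w = weight if lab == "SWS" else None
        independent = _poisson_onsets(rng, iv, rate, p.swr_dur,
                                      p.event_min_sep, weight=w)
        if lab == "SWS" and p.swr_spindle_coupling > 0 and len(spindle_onsets):
            coupled_mask = rng.uniform(size=len(spindle_onsets)) < p.swr_spindle_coupling
            coupled = spindle_onsets[coupled_mask] + p.swr_spindle_lag
            coupled = coupled[(coupled >= iv.starts.min()) &
                              (coupled + p.swr_dur <= iv.ends.max())]
            n_replace = min(len(coupled), len(independent))
            independent = np.sort(np.r_[independent[n_replace:], coupled])
        swr_onsets.append(independent)
    swr_onsets = np.sort(np.concatenate(swr_onsets)) if swr_onsets else np.array([])
    if len(swr_onsets) > 1:    # greedy thinning keeps onsets separable
        keep = [swr_onsets[0]]
        for t0 in swr_onsets[1:]:
            if t0 - keep[-1] >= p.swr_dur + p.event_min_sep:
                keep.append(t0)
        swr_onsets = np.asarray(keep)
    swr_sig, swr_iv = burst_train(n, fs, swr_onsets, p.swr_dur, p.swr_freq,
                                  p.swr_snr * swr_sigma, p.burst_taper, rng)
    pcl = pcl_noise + 0.3 * theta + swr_sig

    lfp = {"srad": srad, "pcl": pcl, "cortex": cortex}
    swr_iv = IntervalSet(swr_iv.starts, swr_iv.ends, ["SWR"] * len(swr_iv))
    spindle_iv = IntervalSet(spindle_iv.starts, spindle_iv.ends,
                             ["spindle"] * len(spindle_iv))
    return lfp, swr_iv, spindle_iv


# ----------------------------------------------------------------------
def _calcium_kernel(fs: float, rise: float, decay: float) -> np.ndarray:
    if decay <= 0:
        raise ValueError("calcium kernel decay must be > 0")
    t = np.arange(0, 6 * decay, 1.0 / fs)
    k = (1.0 - np.exp(-t / max(rise, 1e-6))) * np.exp(-t / decay)
    return k / k.max()


def generate_calcium(params: SimParams, position: np.ndarray,
                     swr: IntervalSet, rng: np.random.Generator
                     ) -> Tuple[np.ndarray, EventTimes, np.ndarray, np.ndarray]:
    """DeltaF/F traces from inhomogeneous Poisson events.

    Returns (traces, true events, place-field centers, cell classes).
    """
    p = params
    fs = p.fs_ca
    n = len(position)
    t = np.arange(n) / fs
    states = p.state_intervals()
    state_of = states.label_at(t + 0.5 / fs)

    # cell classes: hypo / hyper / place / normal
    n_hypo = int(round(p.hypo_frac * p.n_cells))
    n_hyper = int(round(p.hyper_frac * p.n_cells))
    n_place = int(round(p.place_frac * p.n_cells))
    classes = np.array(["normal"] * p.n_cells, dtype=object)
    order = rng.permutation(p.n_cells)
    classes[order[:n_hypo]] = "hypoactive"
    classes[order[n_hypo:n_hypo + n_hyper]] = "hyperactive"
    normal_cells = order[n_hypo + n_hyper:]
    place_cells = normal_cells[:n_place]
    centers = np.full(p.n_cells, np.nan)
    centers[place_cells] = rng.uniform(0.1 * p.track_length,
                                       0.9 * p.track_length, len(place_cells))

    base_rate = np.zeros(n)     # per-second template by state
    for lab, r in p.ca_rates.items():
        base_rate[state_of == lab] = r / 60.0

    run_mask = state_of == "RUN"
    theta_phase = 2 * np.pi * p.theta_freq * t
    lock_gain = 1.0 + p.ca_theta_lock * np.cos(theta_phase)
    theta_states = run_mask | (state_of == "REM")

    dip_gain = np.ones(n)
    if len(swr) and p.swr_ca_dip != 0.0:
        for onset in swr.starts:
            a = int(np.floor((onset + p.dip_window[0]) * fs))
            b = int(np.ceil((onset + p.dip_window[1]) * fs))
            dip_gain[max(a, 0):min(b, n)] = 1.0 + p.swr_ca_dip

    kernel = _calcium_kernel(fs, p.ca_rise, p.ca_decay)
    traces = np.empty((p.n_cells, n))
    refr = max(1, int(round(p.ca_refractory * fs)))
    rows = []
    for i in range(p.n_cells):
        if classes[i] == "hypoactive":
            rate = np.full(n, p.hypo_cell_rate / 60.0)
        elif classes[i] == "hyperactive":
            rate = np.full(n, p.hyper_cell_rate / 60.0)
        else:
            mult = rng.lognormal(0.0, p.rate_spread_sigma)
            rate = base_rate * mult
            if np.isfinite(centers[i]):
                gain = 1.0 + (p.field_gain - 1.0) * np.exp(
                    -0.5 * ((position - centers[i]) / p.field_width) ** 2)
                rate = np.where(run_mask, rate * gain, rate)
        rate = np.where(theta_states, rate * lock_gain, rate) * dip_gain
        spikes = rng.uniform(size=n) < rate / fs
        idx = np.flatnonzero(spikes)
        if len(idx) > 1:    # refractory thinning keeps onsets separable
            keep = [idx[0]]
            for j in idx[1:]:
                if j - keep[-1] >= refr:
                    keep.append(j)
            idx = np.asarray(keep)
        # amplitude expressed in units of the trace noise SD; with zero
        # noise the absolute scale is arbitrary (the detector z-scores)
        noise_unit = p.ca_noise_sd if p.ca_noise_sd > 0 else 1.0
        amps = p.ca_amp_z * noise_unit * rng.lognormal(
            0.0, p.ca_amp_jitter, size=len(idx))
        impulses = np.zeros(n)
        impulses[idx] = amps
        clean = np.convolve(impulses, kernel)[:n]
        # subthreshold theta-band DeltaF/F fluctuation during theta states:
        # the component the trace-LFP coherence analysis measures (amplitude
        # in units of the trace noise SD; phase jittered per cell)
        if p.ca_theta_trace_amp > 0:
            theta_comp = (p.ca_theta_trace_amp * p.ca_noise_sd * np.sqrt(2.0)
                          * np.sin(theta_phase + rng.uniform(0, 2 * np.pi)))
            clean = clean + np.where(theta_states, theta_comp, 0.0)
        traces[i] = clean + (rng.normal(0.0, p.ca_noise_sd, n)
                             if p.ca_noise_sd > 0 else 0.0)
        for j, a in zip(idx, amps):
            rows.append((i, j / fs, j / fs + p.ca_rise, a / noise_unit))
    events = EventTimes.from_records(rows, n_cells=p.n_cells)
    return traces, events, centers, classes


# ----------------------------------------------------------------------
def generate_session(params: Optional[SimParams] = None,
                     seed: Optional[int] = None
                     ) -> Tuple[Session, GroundTruth]:
    """Assemble behavior, LFP and calcium into one validated Session."""
    p = copy.deepcopy(params) if params is not None else SimParams()
    if seed is not None:
        p.seed = seed
    p.validate()
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    position, states = generate_behavior(p, rng)
    lfp, swr_iv, spindle_iv = generate_lfp(p, position, rng)
    traces, events, centers, classes = generate_calcium(p, position, swr_iv, rng)
    session = Session(
        lfp=lfp, ca_traces=traces, position=position,
        track_length=p.track_length, fs_lfp=p.fs_lfp, fs_ca=p.fs_ca,
        meta={"animal_id": f"sim{p.seed}", "genotype": "control",
              "treatment": "none"},
    )
    truth = GroundTruth(states=states, swr=swr_iv, spindles=spindle_iv,
                        events=events, place_fields=centers,
                        cell_class=classes, params=p)
    session.ground_truth = truth
    session.validate()
    return session, truth


# ----------------------------------------------------------------------
def preset_params(kind: str) -> SimParams:
    """Cohort presets. The two presets share every structural parameter and
    differ only in the effect dials: QW event rate, aberrant-cell fractions,
    PAC depth m, SO amplitude, SWR-spindle and SWR-SO coordination, the
    SWR-locked calcium dip, theta-speed slope and calcium theta locking."""
    p = SimParams()
    if kind == "control-like":
        return p
    if kind == "APP-like":
        p.ca_rates = dict(p.ca_rates, QW=0.45)
        p.hyper_frac = 0.10
        p.hypo_frac = 0.18
        p.pac_depth = 0.3
        p.so_amp = 1.2
        p.swr_spindle_coupling = 0.2
        p.swr_so_coupling = False
        p.swr_ca_dip = 0.0
        p.theta_speed_slope = 0.03
        p.ca_theta_lock = 0.4
        p.ca_theta_trace_amp = 0.9
        return p
    raise ValueError(f"unknown preset kind: {kind!r}")


def preset_cohort(kind: str, n_sessions: int, seed: int
                  ) -> List[Tuple[Session, GroundTruth]]:
    """Generate a cohort of preset sessions with per-session derived seeds."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    base = preset_params(kind)
    out = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_sessions) % (2**31 - 1)
    for i in range(n_sessions):
        p = copy.deepcopy(base)
        ses, truth = generate_session(p, seed=int(child_seeds[i]))
        ses.meta["animal_id"] = f"{kind}-{i}"
        ses.meta["genotype"] = "APP/PS1" if kind == "APP-like" else "control"
        out.append((ses, truth))
    return out
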