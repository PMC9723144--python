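"""Analysis configuration.

Every numeric threshold used by the pipeline lives here, with defaults taken
from the study design this package implements: 2 kHz LFP / 20 Hz calcium
sampling, the standard rodent band definitions (delta 0.5-4 Hz, theta 4-10 Hz,
gamma 30-150 Hz, slow oscillation 0.5-1 Hz, spindle 12-16 Hz, ripple
100-300 Hz), the behavioral-state speed/duration/band-ratio rules, and the
event-detection Z thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

Band = Tuple[float, float]


def _default_bands() -> dict:
    return {
        "delta": (0.5, 4.0),
        "theta": (4.0, 10.0),
        "gamma": (30.0, 150.0),
        "so": (0.5, 1.0),
        "spindle": (12.0, 16.0),
        "ripple": (100.0, 300.0),
    }


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with study defaults.

    Durations are seconds, frequencies Hz, rates transients/min, speeds cm/s.
    """

    # sampling
    fs_lfp: float = 2000.0
    fs_ca: float = 20.0
    bands: dict = field(default_factory=_default_bands)

    # behavioral state rules
    run_speed_min: float = 3.0          # RUN: speed > 3 cm/s
    qw_speed_max: float = 0.5           # immobility: speed < 0.5 cm/s
    qw_min_dur: float = 10.0            # QW: immobility > 10 s
    sws_immobility_min: float = 180.0   # SWS: immobility >= 3 min
    sws_delta_theta_ratio: float = 2.0  # SWS: delta/theta power > 2
    rem_theta_delta_ratio: float = 2.0  # REM: theta/delta power > 2
    rem_min_dur: float = 30.0           # REM epochs last >= 30 s
    rem_max_gap: float = 60.0           # REM must start <= 60 s after SWS ends
    state_closing: float = 1.0          # morphological closing of state masks
    ratio_median_window: float = 6.0    # running median on ratio traces
    speed_smooth: float = 0.5           # centered moving average on |dx|*fs
    ratio_window: float = 2.0           # band-ratio sliding window
    ratio_step: float = 0.25            # band-ratio step (display uses 10 ms)

    # calcium event detection
    ca_event_z: float = 2.0             # threshold: 2 Z above the mean
    ca_onset_frac: float = 0.30         # onset at 30% of event peak
    ca_min_sep: float = 0.25            # merge peaks closer than this
    ca_min_dur: float = 0.10            # minimum supra-threshold run
    ca_release_z: float = 0.5           # hysteresis release between events
    ca_confirm_smooth: float = 0.55     # boxcar for the confirmation pass
    hypo_rate: float = 0.25             # hypoactive: < 0.25 transients/min
    hyper_sd: float = 2.0               # hyperactive: > mean + 2 SD of reference
    min_state_dur_for_rate: float = 30.0

    # SWS event detection
    spindle_z: float = 1.25
    spindle_min_dur: float = 0.200
    swr_z: float = 3.0
    swr_min_dur: float = 0.020
    event_merge_gap: float = 0.050
    env_smooth: float = 0.0             # optional Gaussian envelope smoothing
    fir_taps_per_cycle: float = 4.0     # Blackman FIR order = 4 * fs / lo
    fir_max_taps: int = 8192

    # peri-event analyses
    peth_bin: float = 0.030
    peth_window: Band = (-1.0, 1.0)
    power_bin: float = 0.001
    trig_power_window: Band = (-2.0, 2.0)
    at_window: Band = (-0.25, 0.25)
    outside_min_gap: float = 1.0
    ca_trig_bin: float = 0.050
    ca_trig_window: Band = (-5.0, 5.0)
    pre_window: Band = (-5.0, -2.0)
    post_window: Band = (1.0, 2.0)

    # place cells
    spatial_bin: float = 3.0
    occupancy_min: float = 0.5
    place_min_events: int = 5
    n_shuffles: int = 1000
    alpha: float = 0.05

    # spectral estimation
    mt_nw: float = 3.0
    mt_k: int = 5
    seg_len: float = 2.0
    spectrogram_window: float = 2.0
    spectrogram_step: float = 0.010
    psd_fmax: float = 200.0

    # phase-amplitude coupling
    pac_phase_range: Band = (1.0, 25.0)
    pac_amp_range: Band = (1.0, 300.0)
    pac_phase_step: float = 0.5
    pac_amp_step: float = 2.0
    pac_region_default: tuple = ((6.0, 8.0), (60.0, 100.0))
    pac_region_g1: tuple = ((6.0, 8.0), (60.0, 90.0))
    pac_region_g2: tuple = ((6.0, 8.0), (90.0, 150.0))

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> "AnalysisConfig":
        nyq = self.fs_lfp / 2.0
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi <= nyq):
                raise ValueError(f"band {name}=({lo}, {hi}) must satisfy lo < hi <= fs_lfp/2")
        for attr in ("qw_min_dur", "sws_immobility_min", "rem_min_dur",
                     "ca_min_sep", "spindle_min_dur", "swr_min_dur",
                     "peth_bin", "power_bin", "ca_trig_bin", "spatial_bin",
                     "seg_len", "spectrogram_window", "spectrogram_step"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if not 0 < self.ca_onset_frac < 1:
            raise ValueError("ca_onset_frac must be in (0, 1)")
        for region in (self.pac_region_default, self.pac_region_g1, self.pac_region_g2):
            (plo, phi), (alo, ahi) = region
            if not (self.pac_phase_range[0] <= plo < phi <= self.pac_phase_range[1]):
                raise ValueError("PAC region phase bounds outside pac_phase_range")
            if not (self.pac_amp_range[0] <= alo < ahi <= self.pac_amp_range[1]):
                raise ValueError("PAC region amplitude bounds outside pac_amp_range")
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    _TUPLE_FIELDS = ("peth_window", "trig_power_window", "at_window",
                     "ca_trig_window", "pre_window", "post_window",
                     "pac_phase_range", "pac_amp_range")
    _REGION_FIELDS = ("pac_region_default", "pac_region_g1", "pac_region_g2")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        for f in cls._TUPLE_FIELDS:
            if f in d:
                d[f] = tuple(d[f])
        for f in cls._REGION_FIELDS:
            if f in d:
                d[f] = tuple(tuple(pair) for pair in d[f])
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        def listify(x):
            if isinstance(x, tuple):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            return x

        d = listify(self.to_dict())
        if str(path).endswith((".yml", ".yaml")):
            Path(path).write_text(yaml.safe_dump(d))
        else:
            Path(path).write_text(json.dumps(d, indent=2))

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
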