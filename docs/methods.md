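# Methods

This note documents the models, estimators, defaults and numerical choices
behind `ca1pipe`, and what the synthetic-session tests do and do not
establish about recorded data.

## Data model and time conventions

A session couples three streams on one clock: LFP channels (`pcl` =
pyramidal cell layer, `srad` = stratum radiatum, `cortex`) at 2 kHz, a
DeltaF/F matrix (cells x frames) at 20 Hz, and track position (cm) at the
frame rate. All intervals are half-open `[start, end)` in seconds; calcium
frame *k* covers `[k/20, (k+1)/20)`. Validation rejects NaNs, stream-length
mismatches over one frame, and positions outside the track; it repairs
nothing.

## Behavioral state segmentation

States follow the standard speed + band-ratio rules: RUN is speed > 3 cm/s;
immobility is speed < 0.5 cm/s; QW is immobility longer than 10 s; SWS is
immobility with delta/theta power ratio > 2 sustained for at least 3 min;
REM is theta/delta > 2 for at least 30 s arising out of SWS (operationalized
as starting within 60 s of an SWS interval's end — no gap tolerance is
standard, 60 s is permissive enough for brief arousal transitions).

Speed is `|dx| * fs` smoothed with a centered 0.5 s moving average. Band
ratios come from 2 s multitaper windows; the classification trace steps at
0.25 s (the display spectrogram keeps the conventional 2 s / 10 ms). The two
ratio traces are passed through a centered 10-point-per-second running
median over 6 s before thresholding: between sleep stages the ratio jumps by
roughly an order of magnitude, so the median removes single-window flicker
without blurring regime boundaries by more than about a second. An SWS epoch
is a supra-threshold immobility run of at least 180 s, and the median rule
is asserted per emitted epoch; this per-window delimitation is what lets a
contiguous immobility bout containing QW, SWS and REM come apart correctly.
A sustained high-theta epoch with no preceding SWS is left unlabeled rather
than being forced into QW.

On synthetic sessions the classifier's errors are confined to state
boundaries (about 1-1.5 s per transition, from the 2 s ratio window plus the
speed smoothing); pooled per-state frame accuracy across 20 seeded sessions
exceeds 0.98 for every state.

## Calcium event detection

Traces are z-scored against their own full-session mean and SD (plain SD; a
robust estimator would change thresholds for heavily active cells, but the
full-session plain SD is the simplest reproducible reading of a "2 Z above
the mean" rule). A candidate event is a maximal run above 2 Z lasting at
least 0.1 s (two frames). Two further guards make the detector usable at
20 fps in white noise:

- **Hysteresis**: a candidate run only starts a new event if the trace
  returned below 0.5 Z since the previous event. Re-crossings riding on the
  decaying tail of the same transient (decay ~0.5 s) are otherwise counted
  as separate events.
- **Confirmation**: the run must also reach 2 Z on a copy smoothed with a
  0.55 s boxcar (the indicator timescale). Isolated one-or-two-frame noise
  excursions have no mass at that timescale and are rejected; all timing and
  amplitude measurements stay on the raw z-trace.

The event peak is the raw z maximum of the run; the onset is the last time
the raw z-trace rises through 30% of that event's peak before it, with
linear interpolation between frames (sub-frame onsets). Events with peaks
closer than 0.25 s are merged, keeping the larger peak; the merge is
idempotent. With noiseless kernels the detector recovers counts exactly and
onsets within one frame of a dense-grid oracle; with 4 Z transients in unit
white noise, recall and precision are ~0.95-0.99. Transients closer than
about 1.5 s cannot be separated by any threshold detector at this frame
rate and indicator decay; they merge into one event.

Rates are event onsets per minute of state occupancy; a state observed for
under 30 s yields missing values. Hypoactivity is a fixed floor
(< 0.25 transients/min). Hyperactivity is relative: above the reference
population's mean + 2 SD, with reference cells pooled across the reference
animals per state (pooling matches the aggregated-cell proportion tests);
hypoactivity takes precedence when both hold.

## Spectral estimation

All spectra are DPSS multitaper estimates with time-bandwidth NW = 3 and
K = 5 tapers on 2 s segments (the common defaults of the classic multitaper
toolboxes), mean-subtracted per segment, one-sided, and normalized so the
integrated PSD matches the signal variance (checked to 5% against long
stationary signals and against an independent multitaper implementation).
Segments are drawn wholly from within the requested state intervals and
never straddle interval boundaries. Relative band power divides by total
power over [0, 200] Hz. The theta peak is the 4-10 Hz argmax refined by
quadratic interpolation over three bins, ties broken toward the lower
frequency. The theta-power-vs-speed correlation pairs theta power and mean
speed over non-overlapping 1 s RUN windows (Pearson r). Display smoothing
(Gaussian, sigma = 2 Hz) exists only in the plotting helpers and is never
applied before quantification.

## Phase-amplitude coupling

The comodulogram follows the cross-frequency-coherence construction: for
each amplitude frequency fA the raw signal is band-passed at
fA ± max(2, fA/8) Hz (zero-phase), the Hilbert envelope is taken, and the
multitaper coherence between that envelope and the *unfiltered* signal is
read off at the phase frequencies. The bandwidth rule keeps the filter wide
enough above ~16 Hz to pass theta-rate sidebands — a requirement for
envelope-based PAC — while staying narrow at low fA. Grids are 0.5 Hz
(phase, 1-25 Hz) by 2 Hz (amplitude, 1-300 Hz); rows whose band would cross
the Nyquist frequency are skipped with a warning. Values are coherences in
[0, 1] and invariant to amplitude scaling. Scalar PAC is the mean over a
fixed a-priori region (default theta 6-8 Hz x gamma 60-100 Hz; narrow/fast
gamma sub-regions are preconfigured). The surrogate null randomizes the
Fourier phases of each amplitude envelope (magnitudes kept) and recomputes
the region mean; with no injected coupling the observed region mean is a
draw from this null.

## Calcium-LFP coherence

The s. radiatum LFP is low-passed at 0.4 x 20 Hz (zero-phase) and decimated
to the frame rate; coherence per cell uses the same multitaper machinery on
2 s segments within the state. The scalar summary is the maximum coherence
in 4-10 Hz. The continuous DeltaF/F trace is used, not binarized events.
Cell-level group tests pool cells across animals and are flagged as
pseudo-replicated; animal-level means are emitted alongside.

## SWS events

Spindles (12-16 Hz, 1.25 Z, >= 200 ms, cortical channel) and SWRs
(100-300 Hz, 3 Z, >= 20 ms, pyramidal-layer channel) are detected on the
Hilbert envelope of a zero-phase Blackman-windowed FIR band-pass (order
4 x fs / lower-edge, capped at 8192 taps, forced odd so the symmetric
kernel is exactly zero-phase under centered convolution). Z-scoring uses
envelope mean/SD over all SWS samples (not the whole session: wake
theta/movement would inflate the SD). Supra-threshold runs separated by
less than 50 ms belong to one event, and the minimum-duration rule applies
to the event's *total* time above threshold: threshold chatter therefore
never accumulates into an event, and a brief interference dip never splits
one physiological event into sub-duration fragments. Onset is the first
threshold crossing; no emitted event is shorter than its minimum duration.
One caveat of measuring duration on the band-limited envelope: a very
strong burst slightly shorter than the minimum can smear a few ms past it
(the 100-300 Hz filter adds ~2-3 ms per edge), so duration discrimination
is sharp only at detection-grade amplitudes.

The SWR-spindle PETH histograms SWR onsets in [-1, +1] s around spindle
onsets in 30 ms bins, reported as rate per trigger (integer-exact against
brute-force pair counting). Event-triggered band power averages the squared
envelope on a 1 ms grid over [-2, +2] s windows; "at" is the mean over
[-0.25, +0.25] s and "outside" uses matched 0.5 s windows centered at least
1 s from any event (the plotted window bounds are not standardized anywhere;
these are declared defaults and configurable). SWR-triggered calcium
averages DeltaF/F over [-5, +5] s on a 50 ms grid. SWR modulation of event
rates uses pre = [-5, -2] s, at = [-0.25, +0.25] s, post = [+1, +2] s
windows around each SWR onset, with same-class windows merged before
counting so overlapping windows are not double counted; the per-animal
(pre, at, post) triplet feeds a repeated-measures ANOVA.

## Place cells

Tuning curves use 3 cm bins per running direction (direction = sign of
velocity among frames with speed > 3 cm/s; the two directions partition RUN
frames exactly). Rates are counts/occupancy for bins occupied at least
0.5 s. Spatial information is the Skaggs bits-per-event form
SI = sum_i p_i (lambda_i/lambda_bar) log2(lambda_i/lambda_bar). The null
redraws each event's frame uniformly over the direction's RUN frames
(occupancy-weighted by construction), 1000 shuffles by default, with
p = (1 + #{SI_null >= SI}) / (n + 1); a cell is a place cell at p < 0.05 in
either direction. No curve smoothing is applied before SI. Cells with fewer
than 5 direction events are flagged non-place rather than erroring. Each
per-direction test is calibrated (type-I at the nominal 5%); the cell-level
either-direction rule doubles the exposure by construction
(1 - 0.95^2 ~ 9.8% of untuned cells), the usual cost of testing both
directions without correction. At
20 fps the test has high power only for strong, well-sampled fields
(in-field gain ~6 with ~12 cm fields and ~50 events per direction detects
>= 90%; gain 3-4 or ~25 events detects roughly half); each direction-test's
type-I rate sits at the nominal 5%.

## Group statistics

One-way repeated-measures ANOVA (sphericity assumed, matching plain
F-dfs), computed via pingouin and cross-checked in the tests against an
explicit sums-of-squares oracle; post-hoc pairwise paired t-tests are
reported unadjusted (the comparable convention) with Holm-adjusted values
alongside. Student's t (paired/unpaired, 1- or 2-sided), Pearson chi-square
without continuity correction (df = 1), and two-sample Kolmogorov-Smirnov
(asymptotic p) cover the remaining comparisons. Type-I rates of all tests
are verified at alpha = 0.05 on matched-null simulations.

## The synthetic-session generator

The generator is first-class, tested code: every analysis stage is verified
against sessions whose ground truth (state schedule, burst intervals, event
times, place-field map) is known by construction.

- **Behavior**: back-and-forth traversals of a 200 cm track at
  15 ± 7 cm/s (sinusoidally varying) during RUN; sub-threshold positional
  jitter elsewhere. Default schedule: RUN 360 s, QW 180 s, SWS 360 s,
  REM 90 s (~15.5 min) — long enough for every stage's preconditions
  (>= 10 s QW floor, >= 180 s SWS, >= 30 s REM, >= 60 s of RUN for PAC and
  coherence) while keeping full-cohort analyses desk-scale.
- **LFP**: 1/f Gaussian background (exponent 1, unit SD) on all channels.
  s. radiatum carries theta (7 Hz sinusoid; per-state amplitudes 2.0 / 0.8 /
  0.2 / 2.5 for RUN/QW/SWS/REM plus 0.1 amplitude per cm/s of speed in RUN),
  a delta-band noise component (0.3 / 0.48 / 2.5 / 0.15), and gamma.
  Per-state amplitudes were set so each state satisfies its defining ratio
  with margin *after* accounting for the 1/f background (which alone carries
  more delta- than theta-band power) and for multitaper smearing — the SWS
  delta carrier is kept below 3 Hz so ±1.5 Hz smearing cannot leak it into
  the theta estimate, and QW is balanced near ratio 1 so neither threshold
  is approached. Gamma is a Gaussian-spectral-profile noise carrier
  (center 80 Hz, FWHM 20 Hz — no brick-wall band edges, which would
  concentrate modulation sidebands at the edge and displace the
  comodulogram peak) whose envelope is multiplied by (1 + m cos(theta
  phase)); m in [0, 1] is the single PAC dial.
- **SWS events**: SWRs (140 Hz, 50 ms) and spindles (14 Hz, 500 ms) are
  flat-top Tukey-windowed (20% taper) sinusoid packets: the taper keeps the
  true onset sharp (threshold crossing within ~4 ms of packet start) while
  avoiding spectral splatter. A fully tapered (Hann) packet at these SNRs
  would cross threshold only ~15 ms after its nominal onset and hold it for
  under 20 ms, making onset-error and duration accounting ill-posed.
  Packet amplitude is expressed relative to the in-band SD of the background
  (SWR default 5x; spindle default 8x — at the low 1.25 Z spindle threshold,
  weaker packets would be inseparable in principle from the ~0.25 s
  correlation-time envelope excursions of a 4 Hz-wide band). The slow
  oscillation is a 0.75 Hz sinusoid with slow (0.04 Hz, depth 0.6) amplitude
  modulation; SWR-SO coordination places SWRs preferentially at high SO
  amplitude, and a configurable fraction of spindles (default 0.7) receives
  an SWR 0.1 s before onset.
- **Calcium**: per-cell inhomogeneous Poisson events (state rates 1.5 / 0.9 /
  0.7 / 0.6 per min with lognormal cell spread 0.4), convolved with a
  rise-0.07 s / decay-0.5 s kernel (amplitude 5x the trace noise SD 0.2,
  10% lognormal jitter) plus white noise. A 0.3 s refractory keeps true
  onsets separable. Hypo- (8%, 0.1/min) and hyperactive (2%, 5/min)
  subpopulations, Gaussian place fields (30% of cells, 12 cm SD, gain 6)
  during RUN, an optional rate dip in ±0.5 s windows around SWR onsets
  (default -40%), theta-phase rate modulation, and a subthreshold theta-band
  DeltaF/F component (SD 0.5x noise SD during theta states). The last item
  is the component the trace-LFP coherence measures: pure rate modulation is
  invisible in coherence at 20 fps because the indicator kernel attenuates
  the 7 Hz line ~20-fold below the white trace noise.
- **Cohort presets**: `control-like` and `APP-like` share all structural
  parameters and differ only in effect dials (QW rate 0.9 vs 0.45/min;
  hyper fraction 2% vs 10%; hypo fraction 8% vs 18%; PAC depth 0.8 vs 0.3;
  SO amplitude 2.5 vs 1.2; spindle-SWR coupling 0.7 vs 0.2; SWR-SO coupling
  on vs off; SWR calcium dip -40% vs 0; theta-speed slope 0.1 vs 0.03;
  theta trace amplitude 0.5 vs 0.9). Magnitudes are configurable; defaults
  were chosen once to be detectable at 6-7 sessions per group, mirroring
  the direction of every group effect the pipeline is meant to expose.

Everything is a deterministic function of (params, seed). What the
generator does **not** emulate: miniscope optical crosstalk and neuropil
contamination, movement artifacts, electrode drift, non-sinusoidal theta
waveform asymmetry, ripple-frequency dynamics, EMG realism, and real sleep
architecture (state bouts follow the schedule exactly). Passing recovery
tests therefore demonstrates the estimators' correctness under the model's
assumptions, not robustness to these artifacts.

## Numerical choices and degenerate inputs

Zero-variance traces yield zero events / undefined coherence with a
warning, never an exception mid-pipeline. Flat in-band spectra return NaN
peaks with a warning. All-zero LFP is a hard "degenerate" error. FFT-based
filters and envelopes pad to fast FFT lengths and truncate back. Shuffle
and surrogate counts use the +1 Monte Carlo correction. Event detectors
apply duration rules before merge rules. Chi-square tables must have
positive marginals; degenerate t-tests (zero pooled variance) are errors.

## Problem sizes in the shipped tests

The test-suite and acceptance-script runs use: 10-minute single-state
records with 100 injected events for detector recovery; 10-20 sessions for
state-classifier accuracy; 180 s RUN blocks for PAC (full 1-300 Hz matrix,
100 surrogates) and coherence; 200 null cells at 200 shuffles for the
place-cell type-I check; and 6-7 sessions per preset cohort for the group
contrasts. These sizes give Poisson/binomial margins comfortably inside the
asserted tolerances.
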