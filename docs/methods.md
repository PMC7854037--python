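# Methods

`exemg` re-creates, as a headless library, the computational core of an
EMG-driven exergaming system for wheelchair users: wireless surface-EMG
envelope sensors worn on the arm drive three exercise games, and cloud
session logs feed usage and energy analytics. This note documents the
models, the defaults and why they were chosen, and what the synthetic
data can and cannot show.

## Signal model

The emulated sensor does its signal conditioning on board and transmits
a *linear envelope* — full-wave rectified EMG through a 2-pole low-pass
filter — at 64 Hz with a 15-bit ADC. Streams (`EmgStream`) therefore
carry non-negative envelope amplitudes, not raw EMG; every downstream
consumer is written against envelopes. Amplitudes are treated as mV
throughout. The hardware's printed dynamic range (0–60) is ambiguous
about units, so no hardware fidelity is asserted; the default range is
only used for optional ADC-grid quantization.

`extract_envelope` is provided for raw-like signals: rectification
followed by a causal 2nd-order Butterworth low-pass with unit DC gain,
clamped at zero (an IIR filter can undershoot transients, a physical
envelope cannot). The cutoff is not published for the hardware;
the default is **3 Hz**, a conventional choice for EMG linear
envelopes, and everything downstream is cutoff-agnostic. Tests verify
unit DC gain, ≥ 30 dB ripple suppression one decade above cutoff, and
the −40 dB/decade asymptote against the analytic second-order
magnitude response.

## Synthetic streams

The study's recordings were never deposited, so streams are generated
from a burst model: a resting noise floor plus non-overlapping
trapezoidal bursts (linear rise, plateau, linear fall) with
multiplicative Gaussian jitter `x·(1 + σ·N(0,1))` clipped at zero.
Trapezoids are the simplest shape giving MVC-like plateaus, ramped
onsets for the hysteresis detector, and a measurable floor. Generation
is bitwise reproducible per seed.

What this emulates: contraction bursts over a quiet baseline, sensor
jitter, plateau effort levels. What it does not: motion artifacts,
electrode lift-off, fatigue-related spectral drift, crosstalk between
muscles, or realistic inter-contraction variability. Passing tests
therefore demonstrate correctness of the *processing*, not robustness
to messy field data.

## Calibration and goals

Calibration runs **3 maximum voluntary contraction (MVC) trials** per
muscle (bicep, tricep, anterior deltoid, posterior deltoid). Per trial,
the effort level is the best mean over a **3-second** window, slid at
sample resolution so the result is invariant to when in the trial the
contraction happened. How the three trial values combine into one MVC
was an open choice; the default is the **maximum** (standard MVC
practice), with `mean` and `last` available for sensitivity analysis
and all trial values retained for audit.

The resting noise floor is the **median** of a burst-free rest
recording — robust to stray artifacts, matching how a technician reads
an empirical baseline.

Default thresholds, as fractions of MVC:

| game         | upper | lower        |
|--------------|-------|--------------|
| high striker | 0.90  | 0.20         |
| boxing       | 0.80  | 0.30         |
| racing       | 1.00  | noise floor  |

The goal store (`GoalSet`) persists per-(game, muscle) pairs as JSON;
user overrides are accepted subject only to `0 ≤ lower < upper`.

## Contraction detection

Detection is dual-threshold hysteresis on the envelope: an event opens
when the envelope rises to the **lower** threshold and closes when it
falls back below; the **upper** threshold classifies success (bell /
valid punch) without gating detection, so a repetition that misses the
target is still counted — reps and target hits are reported separately.
Both comparisons are closed (`≥`) for deterministic tie-breaking. A
contraction still open at stream end is closed there and flagged
`truncated`.

Events whose below-threshold gap is shorter than a refractory interval
(default **0.25 s**) merge into one; at 64 Hz this suppresses chatter
without hiding a fast boxing cadence. Note one consequence: the event
*count* is not in general monotone in the lower threshold. Raising the
threshold shrinks event spans, which can widen a gap past the
refractory interval and split a previously merged pair (and for
arbitrary multimodal envelopes a raised threshold can split a bimodal
event regardless of merging). For well-separated unimodal bursts with
merging disabled, monotonicity holds and is property-tested in that
form.

iEMG is the trapezoidal integral of the envelope — exact for the
piecewise-linear interpolant and additive at shared sample points, so
event integrals plus gap integrals tile exactly to the whole-session
integral. The last sample of a stream is held for one sample period so
a whole-stream integral spans the full duration. For a discontinuous
rectangular pulse of amplitude A, any sample-based quadrature carries
an O(A·dt) edge error (dt = 1/64 s); tests assert the analytic A×T to
within one sample period.

## Game engines

All three engines are pure functions of (stream, config, MVC): no
clocks, no randomness, bit-identical replays. They consume samples in
chunks of any size with exact streaming/batch equivalence (the
whole-session integral is accumulated sequentially per sample for this
reason), and emit feedback events in place of the app's audio-visual
cues.

**High striker** (resistance-band sets). Each detected contraction
raises a bar; the bar fraction is `min(1, iEMG / (MVC ×
reference_duration))` with the reference defaulting to the 3 s
calibration window — i.e. a contraction worth 3 s of sustained MVC
fills the bar. The bell is governed by the 90 %-MVC upper target on
peak amplitude by default; whether the original app's bell followed
peak amplitude or bar saturation is ambiguous, so both rules are
implemented (`bell_rule="peak" | "bar"`).

**Boxing**. 30 valid punches advance the round; 3 rounds total. A
punch is a contraction whose peak reaches the current round's
threshold. The per-round values were never published beyond "the
threshold increased each round"; the default schedule interpolates
linearly from the lower to the upper goal across rounds —
{0.30, 0.55, 0.80}×MVC with default goals — and an explicit
non-decreasing schedule can be configured. Completing rounds 1 and 2
emits `round_advanced`; completing round 3 emits `game_over`.

**Racing**. Per sample, effort = `clamp(envelope/MVC, 0, upper/MVC)`,
zeroed below the lower threshold (the noise floor, so the car never
creeps at rest). Angular position advances by `gain · effort · dt`; a
lap is 2π. The speed constant was never published; the gain is
calibrated so sustained 100 % effort yields a configurable reference
lap time (default **10 s/lap**), giving the closed form `lap time =
2π/(gain · effort)`, which tests verify to within a sample period.
"One final lap!" fires when one lap remains. Ghost replay runs two
streams through identical kinematics and compares finish times.

Energy/MET displays are not computed in the engines — they only
accumulate iEMG; the analytics module owns the energy mapping.

## Session analytics

Sessions persist as one JSON per login span plus an index CSV, with a
deterministic writer (fixed key order, repr floats) so write → read →
write is byte-identical. Weekly rollups are user-relative (week 0
starts at each user's first login) and count only game-engine-active
spans as exergaming, splitting "time on app" from "time exergaming".
Overlapping sessions for one user are rejected as a data-integrity
error.

iEMG-vs-time association uses the standard Pearson product-moment
coefficient, per game and pooled, on per-session pairs by default
(per-week aggregation is also provided; which pairing the original
analysis used is unstated). iEMG rises linearly with energy
expenditure, so the energy proxy is an affine map with default
coefficients (1, 0) in arbitrary units — a monotone proxy, not a
validated kilocalorie measurement. Likert summaries report mean and
sample SD (n−1, the small-questionnaire convention); a single response
has no defined sample SD and is reported as missing.

## Synthetic cohort

`generate_cohort` emulates the pilot's shape for the analytics: 4
users × 8 weeks, 3 sessions/week (a 3×45-minute weekly workout was the
recommendation), per-user mean weekly app minutes drawn uniformly over
89–267 (the reported cohort span, averaging ≈146), exergaming fraction
normal around 0.53 (reported range 0.39–0.59), and per-game-session
iEMG proportional to exergaming minutes (18 mV·s/min ≈ a 0.3 mV mean
envelope; arbitrary units) with 8 % multiplicative noise. By
construction this reproduces the qualitative iEMG-vs-time
proportionality (r > 0.95 on synthetic cohorts); it does not reproduce
the four real participants' numbers, which depend on undeposited
recordings. The generator returns a ground-truth ledger so tests check
the analytics against bookkeeping, not against the code under test.

## Numerical and scale choices

* All quadrature is trapezoidal; sequential accumulation where exact
  chunk-invariance is required.
* Closed thresholds (`≥`) everywhere; sample-index ↔ time mapping is
  `i / rate`, 0-based.
* Degenerate inputs fail loudly: empty rest streams, trials shorter
  than the window, MVC ≤ noise floor, inverted thresholds, overlapping
  bursts or sessions, zero-variance correlations.
* Test problem sizes (streams of seconds to a couple of minutes at
  64 Hz, 1,000-stream oracle sweeps, 4×8-week cohorts) were chosen as
  the smallest sizes at which every property is exercised at full
  sample rate; the whole suite runs in a few seconds.

## Known limitations

* The burst generator's realism limits (above); no heart-rate or
  accelerometer channels (heart rate appears only as optional scalar
  metadata in summaries, never as a computed quantity).
* Boxing round thresholds and the racing speed constant are package
  defaults, declared as such — not inferred values of the original app.
* The energy proxy is uncalibrated by default.
* No real-time loop: engines process recorded or generated streams;
  latency and transport are out of scope.
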