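# Methods

This note records the models, defaults, and numerical conventions behind
`legforce`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signals and units

All forces are in body weights (BW; 1 BW = body mass × g), the unit in
which participants see and control the signal. Force and target share a
1000 Hz clock; EMG runs at 2000 Hz and is shifted onto the force clock by
the 500 µs wireless transmission delay (exactly one EMG sample, so the
default correction is a pure integer shift). Analysis windows are
half-open `[start, end)` on the segment clock; exclusion-criterion windows
are closed (edge ties count as inside). Threshold crossings are located by
linear interpolation between samples under a first-crossing rule, which is
deterministic and robust to the sampling grid (metrics on a 10× resampled
copy agree within 1 ms / 0.1 percentage point).

## Filtering

Force is low-passed at 10 Hz (4th-order Butterworth) before any metric is
computed — this is the signal the participants saw and tracked. The filter
runs zero-lag (forward–backward, squaring the magnitude response) so rise
and fall estimates carry no group delay; a causal mode and a raw-force
switch exist in the config (`force_filter.{zero_lag, enabled}`). Segments
are padded by reflection over roughly one settling length of the slowest
pole before the forward–backward passes, keeping transients out of the
first analysis window. EMG is band-passed 30–400 Hz and band-stopped
59–61 Hz, both 4th-order zero-lag. `order` means the design order of one
pass throughout.

## Response metrics

Rise time is the interpolated interval between the first crossings of
baseline + 10% and baseline + 90% of the step size, searched in
[onset − 0.5 s, onset + 1 s); bandwidth is 0.35 / rise time (s), so
bandwidth × rise time ≡ 0.35 for every computed pair. Because 1/x is
convex, the mean of per-response bandwidths exceeds 0.35 over the mean
rise time — both are reported, neither is derived from the other's mean.
Fall time mirrors the rise between segment seconds 4 and 6 (step) or from
the pulse end to the segment end (pulse; the convention for pulses is a
config choice, `metrics.fall_window_s` for steps). Overshoot is signed and
not clamped: clamping at zero would bias condition means upward.
Steady-state windows run from onset + 2 s to onset + 4 s — the second half
of the 4-s on-phase, after settling. Metrics that cannot be computed (a
threshold never crossed inside its window) are NaN with a per-metric flag,
and propagate as missing cells handled by listwise deletion in the ANOVA
(logged); they are not imputed.

## Response screening

Four step criteria and two pulse criteria remove responses that do not
describe a reaction to the target transition. The operational definitions
matter more than usual here because fatigue multiplies tremor:

- The response's **step-up instant** is the last crossing of the 10% level
  that precedes the half-rise point — the crossing *connected to the
  actual rise*. Anchoring to any threshold crossing in a window would let
  band-limited tremor (≈3% CV at the final fatigue stage) trigger the
  early-rise and no-rise criteria on ordinary responses.
- **Early rise**: step-up at or before 0.5 s pre-onset (0.25 s for
  pulses). A sustained early rise necessarily elevates the pre-onset mean,
  so it also flags elevated baseline.
- **No rise**: the step-up has not occurred by onset + 0.5 s. The 10%
  level is used, not 90%: requiring 90% within 0.5 s would reject most
  legitimately slowed fatigued responses (mean rise ≈ 370 ms starting
  ~0.2 s after onset), which is irreconcilable with the near-zero
  exclusion rates such experiments report. Configurable
  (`exclusion.no_rise_frac`).
- **Elevated baseline / early fall**: window *means* against the 10% level
  over the 0.5 s pre-onset and the final 1 s of the on-phase — level
  criteria, robust to single-sample excursions.
- **Pulse late fall**: the descent *onset* (first drop below the 90%
  level, `exclusion.pulse_fall_frac`) must occur within 0.5 s of the pulse
  end. Onset rather than completion: a fall that merely takes a few
  hundred ms to complete is an ordinary response, not a held one. A pulse
  that never reached the 90% level has no descent to be late; it simply
  yields no rise/fall metrics.

Screening runs on the same filtered force as the metrics and is a pure
function of one segment plus thresholds.

## Statistics

Per participant × condition, each step characteristic is the mean of the
first five non-excluded responses in trial order after the condition's
final MVC (cells with fewer are averaged over what exists and flagged).
The omnibus test is the classical one-way repeated-measures decomposition,
F = MS_condition / MS_condition×subject on (k−1, (k−1)(n−1)) df,
implemented directly from the sums of squares and cross-checked in the
test suite against statsmodels' `AnovaRM`; a null simulation keeps its
type-I error at the nominal 5%. No sphericity correction by default
(Greenhouse–Geisser behind `stats.sphericity_correction`). Significant
omnibus effects are followed by paired two-sided t-tests over all
C(5,2) = 10 condition pairs with Bonferroni correction (factor = number of
pairs, capped at 1, never below the raw p). Effect sizes are pooled-SD
Cohen's d, (m₁ − m₂)/√((s₁² + s₂²)/2), labeled small/medium/large at
0.2/0.5/0.8. The pulse task is compared Pre-Fatigue vs Fatigue-3 only, by
paired t-test. Degenerate zero-variance contrasts report p ∈ {0, 1} and
are flagged rather than passed to a t distribution.

## The synthetic participant

The generator exists to give every pipeline stage a ground truth. The
simulated controller is a pure motor delay (100 ms; anticipatory preview
makes this shorter than a naive visuomotor latency) followed by a linear
second-order plant, discretized with a zero-order hold at the trace rate —
exact for piecewise-constant commands, so noiseless runs reproduce the
closed-form step response to float precision. Its two parameters map
one-to-one onto the measured quantities: the natural period (default
0.8852 s, calibrated so the noiseless 10–90% rise is 303 ms) sets rise
time; the damping ratio (0.708, giving the canonical 4.3% peak overshoot)
sets overshoot. Output saturates at the participant's maximal force
(2.95 BW default), which is how MVC trials measure the programmed maximum
regardless of the unattainable 5 BW display target. MVC and hold commands
ramp over ~3 s and ~2 s respectively (people build force gradually even
against a constant target); the hold level is 1 BW + 25% of the
participant's pre-fatigue maximum.

**Noise.** Variability is Gaussian, band-limited below 8 Hz
(physiological force fluctuations sit well under the 10 Hz display
filter), with SD = `noise_cv` · (max(force − 1 BW, 0) + 0.1 BW): tremor
scales with *active* drive above passive standing support, not with total
vertical load. Proportional-to-total-force noise would put ≈0.035 BW of
tremor on the between-step baseline against a 0.04 BW screening margin,
excluding most fatigued responses and corrupting the rise window — neither
happens in real data. `noise_cv` defaults to 0.0148, placing the measured
final-10-s hold CV at 0.61% after the display filter. Additive linear
drift is available (`drift_per_s`) but defaults to 0: participants
visually null slow error, and open-loop drift of any visible size trips
the baseline criteria. Fatigue scales the noise in hold and MVC trials
only; variability growth is a sustained-contraction phenomenon, and
accuracy metrics in the step task are empirically preserved under fatigue.

**Pulse behavior.** Pulses are modeled as brief feedforward pushes: the
0.05-s target is internally widened to 0.462 of the pulse plant's natural
period (scaling with the participant, so slow responders still near the
target), driven through a plant 0.473× the step-task period with a 50 ms
anticipatory delay. This lands the cohort pulse rise near 148 ms. Fatigue
multipliers are not applied to pulse trials, emulating the resilience of
feedforward control. Consequence of the symmetric linear plant: synthetic
pulse and step fall times roughly equal the rise times, underestimating
the slower falls real participants produce; fall-time condition effects in
synthetic sessions therefore mirror the programmed rise slowing rather
than any independent fall behavior.

**EMG.** Each muscle is unit-variance Gaussian noise shaped to an ideally
flat per-muscle band (midpoints at typical baseline median frequencies,
e.g. gastrocnemii ≈126–133 Hz, biceps femoris ≈90 Hz), amplitude-modulated
by the force envelope (5×10⁻⁴ V/BW). Spectral fatigue multiplies the band
edges: a scalar shift masks the shifted band directly; a within-trial ramp
reads fixed-band noise at a time-varying rate, which scales every
instantaneous frequency by the ramp value. Median frequency therefore
scales exactly with the programmed shift, up to a ≈1 pp upward bias at the
strongest compression from the 30 Hz band-pass edge and the 59–61 Hz
notch clipping the shifted band's lower tail.

**Fatigue profile and cohort.** Per-condition multipliers on maximal
force, natural period, noise, and EMG spectral position default to
(1, 1, …) for Training/Pre-Fatigue and reach 0.739 / 1.233 / 4.6 / 0.897
at Fatigue-3 — the effect magnitudes the analysis is designed to detect —
with roughly geometric intermediates. The EMG shift ramps linearly across
each condition's three holds from the previous condition's value, so the
"first 10 s of the initial hold" baseline is genuinely unfatigued.
Participants are drawn once per session: body mass N(74, 16) kg, natural
period and noise lognormal (σ = 0.30, 0.45), maximal force N(2.95, 0.58)
BW, damping lognormal (σ = 0.07), plus a shared lognormal fatigue
susceptibility exponent (σ = 0.25, mean exactly 1 so programmed group
ratios are unbiased) and a 5% per-trial period jitter. Per-trial seeds
derive from a stable hash of (master seed, participant, condition, task,
repetition).

## Protocol

Training: 2 MVC + 3 Step. Pre-Fatigue: 2 MVC + 3 Step + 2 Pulse + one
practice Hold (the baseline for hold variability). Each fatigue
condition: (Hold + MVC) × 3, then 3 Step; 2 Pulse after Fatigue-3. The
condition-level MVC is the final MVC of the condition. EMG generation is
selectable per hold (`emg_policy`): every hold, only the endpoint holds
(first of Fatigue-1, last of Fatigue-3 — all the median-frequency
comparison needs), or none; tests and the acceptance script use the
endpoint policy to keep runtimes in seconds per cohort.

## Pre-registered recovery bands

Programmed-effect recovery is asserted on seed-means over 20 independent
18-participant sessions, with bands frozen from a pilot before the
acceptance suite ran: MVC decline [23.1, 29.1]% (26.1 ± 3), rise-time
ratio [1.15, 1.35], hold-CV ratio [3.9, 5.3] (4.6 ± 15%), median-frequency
drop [7.8, 12.8]% (the programmed ≈10.2% minus the known ≈1 pp band-edge
bias), omnibus rise-time rejection in ≥80% of seeds at α = 0.05. Known
small biases inside the bands: the first-crossing rule under fatigue-level
tremor shaves a few ms more off the slower 90% crossing than the faster
10% one, pulling the measured rise ratio slightly below the programmed
1.233; MVC truncation at the 1.7 BW draw floor trims ~1 pp off the
programmed decline.

## What passing tests do and do not show

The generator shares the pipeline's world-view (piecewise-linear signals,
stationary band-limited tremor, linear plant, flat EMG bands). Passing
recovery tests shows the pipeline measures what was programmed, at study
scale, through the full protocol — it does not validate the plant as a
model of the nervous system (no reflex loops, no motor-unit dynamics, no
learning, no co-contraction), nor the noise model beyond its first two
moments, nor EMG beyond its spectral centroid behavior. Measured overshoot
on noisy synthetic data (~6–7%) exceeds the noiseless plant's 4.3% because
a window maximum rides on tremor peaks; the same mechanism operates on
real data, so cross-condition comparisons — the quantities that matter —
are unaffected. Real recordings additionally contain artifacts the
generator does not emulate (electrode motion, cross-talk, rig compliance);
the screening criteria and the CSV contract are the only defenses the
package offers against them.
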