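# legforce

Analysis pipeline for **leg external-force control under neuromuscular
fatigue**: how quickly and how accurately can the nervous system modulate
the vertical ground-reaction force, and which of these abilities does
fatigue impair?

The package targets force-matching experiments in which a participant
stands on one leg on a force plate (1000 Hz) and matches visual targets
expressed in body weights (BW), with optional six-channel surface EMG
(2000 Hz), across five protocol conditions (Training, Pre-Fatigue,
Fatigue-1/2/3; fatigue induced by sustained submaximal holds). It is aimed
at motor-control and biomechanics researchers who need the full chain —
filtering, response segmentation, screening, metrics, spectral fatigue
indices, condition-level statistics — as tested, reusable code, plus a
synthetic-session generator that supplies ground truth for every stage.

## What is computed

For each step (1.0 → 1.4 BW, 4 s on / 3 s off) or brief pulse (0.05 s)
response, with all thresholds expressed relative to the step size
ΔF = 0.4 BW and located by linearly interpolated first crossings:

- **rise time** `t_r` — time from 10% to 90% of ΔF (ms), searched from
  0.5 s before to 1 s after the target step-up;
- **bandwidth** `f_bw = 0.35 / t_r` (Hz), the first-order estimate of the
  highest trackable target frequency;
- **fall time** — 90% → 10% of ΔF around the target step-down;
- **overshoot** — 100 · (peak − target) / ΔF, signed;
- **steady-state error / variability** — |mean − target| / target and
  CV (%) over onset + 2…4 s.

Whole-trial fatigue markers: MVC mean force over 4–8 s of a maximal push;
hold-task steadiness as CV % per 1-s window (first 5 s discarded, final
10 s summarized); EMG median frequency (the half-power frequency of the
30–400 Hz periodogram) per 2-s window, with fatigue summarized as the
percent drop from the first 10 s of the initial hold to the final 10 s of
the last hold. Responses failing the screening criteria (early rise, no
rise, elevated baseline, early fall; pulse: early rise, late fall) are
flagged and excluded. Per participant and condition, each characteristic
is averaged over the first five usable responses after the condition's
final MVC, then compared across the five conditions with a one-way
repeated-measures ANOVA (F = MS_condition / MS_condition×subject),
Bonferroni-corrected paired contrasts, and pooled-SD Cohen's *d*.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
18-participant cohort (seed 1) and write tables under `results/session/`:

```bash
python analysis/01_simulate_session.py   # protocol + on-disk format demo
python analysis/02_run_pipeline.py       # simulate + analyze the cohort
python analysis/03_fatigue_markers.py    # MVC, hold CV, EMG median frequency
python analysis/04_condition_statistics.py
```

`02_run_pipeline.py` prints the Pre-Fatigue operating point:

```
Processed 756/756 trials (0 failed)
Responses screened: 0 of 3420 excluded (none)

Pre-Fatigue step responses (all 30 per participant):
  rise_time_ms                    303.58 +/- 71.35 ms
  bandwidth_hz                      1.23 +/- 0.34 Hz
  fall_time_ms                    304.78 +/- 81.49 ms
  overshoot_pct                     6.34 +/- 2.31 %
  steady_state_error_pct            0.08 +/- 0.07 %
  steady_state_variability_pct      0.51 +/- 0.20 %
```

— a cohort that rises to a 0.4 BW step in ~300 ms (bandwidth ~1.2 Hz;
note the mean of per-response bandwidths exceeds 0.35 over the mean rise
time, a Jensen-inequality effect) and settles within a fraction of a
percent of the target. `04_condition_statistics.py` then shows the
dissociation the pipeline is built to detect:

```
  rise_time_ms                   F(4,68) =    36.22, p = 3.41e-16  *
  bandwidth_hz                   F(4,68) =    41.55, p = 1.38e-17  *
  overshoot_pct                  F(4,68) =     2.26, p = 0.0719
  steady_state_error_pct         F(4,68) =     0.79, p = 0.533
  ...
Pulse task, Pre-Fatigue vs Fatigue-3 (paired t):
  rise_time_ms                    143.58 ->  146.14, p = 0.299, d = -0.07
```

Responsiveness (rise time, bandwidth) degrades across fatigue conditions
while accuracy metrics do not move, and the feedforward-dominated pulse
task is spared; MVC falls ~24% and hold CV grows ~4.3-fold
(`03_fatigue_markers.py`).

There is also a CLI over the same pipeline:

```bash
legforce synth --seed 1 --out trials/         # write a synthetic study
legforce run   --in trials/ --out results/    # analyze a directory of trials
legforce report --results results/
```

Real recordings enter through the documented CSV contract
(`time_s, force_bw, target_bw` + a JSON sidecar with participant,
condition, task, body weight, and target onset metadata; EMG as
`time_s, <muscle>…` at 2000 Hz).

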