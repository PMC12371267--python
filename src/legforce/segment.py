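"""Cut step/pulse trials into onset-aligned response segments and screen them.

Segmentation anchors exclusively to the *target* step-up times carried in
trial metadata -- never to the force signal.  A step segment spans 6 s
(1 s before the step-up, 4 s on, 1 s after the step-down); a pulse segment
spans 3 s centered on the 0.05-s pulse (1.5 s of context either side).

Four step criteria (early rise, no rise, elevated baseline, early fall) and
two pulse criteria (early rise, late fall) remove responses that do not
describe a genuine reaction to the target transition.  The response's
"step-up" instant is the last crossing of baseline + 10% of the step size
that precedes the half-rise point -- anchoring to the crossing *connected
to the actual rise* makes the screen robust to transient noise excursions
over the threshold, which matters once fatigue multiplies force
variability.  Level criteria (elevated baseline, early fall) compare window
means against the same threshold.  Criterion windows are anchored to target
transitions with edge ties counted as inside (closed intervals).  Decisions
are pure functions of one segment plus thresholds, evaluated on the same
filtered force the metrics use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, ExclusionConfig
from .events import first_crossing, last_crossing_at_or_before, window_values_closed
from .trace import Condition, SampledTrace, Task, TrialRecord

__all__ = [
    "ResponseSegment",
    "ExclusionFlags",
    "SegmentationError",
    "segment_step_task",
    "segment_pulse_task",
    "apply_step_exclusions",
    "apply_pulse_exclusions",
]

#: Context carried around a step-up: (before step-up, after step-down).
STEP_MARGINS_S = (1.0, 1.0)
#: A pulse segment is 3 s: 1.5 s before the step-up to 1.5 s after it.
PULSE_MARGIN_S = 1.5

_EDGE = 1e-9  # closed-interval tolerance at criterion window edges


class SegmentationError(ValueError):
    """A trial could not be cut into the expected response segments."""


@dataclass
class ResponseSegment:
    """A windowed, onset-aligned excerpt of one step or pulse response.

    The excerpt clock starts at 0; the target step-up sits at
    ``onset_seg_s`` (1.0 s for steps, 1.5 s for pulses) and the step-down at
    ``stepdown_seg_s``.  ``window_trial_s`` records where the excerpt came
    from on the parent trial's clock.
    """

    participant_id: str
    condition: Condition
    task: Task
    repetition: int
    step_index: int
    window_trial_s: tuple[float, float]
    onset_trial_s: float
    onset_seg_s: float
    stepdown_seg_s: float
    baseline_bw: float
    step_size_bw: float
    force: SampledTrace
    target: SampledTrace

    def __post_init__(self) -> None:
        if self.step_size_bw <= 0:
            raise ValueError(f"step_size_bw must be > 0, got {self.step_size_bw}")


@dataclass(frozen=True)
class ExclusionFlags:
    """Outcome of screening one segment; excluded iff any reason fired."""

    excluded: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded must be True exactly when reasons is non-empty")

    @classmethod
    def from_reasons(cls, reasons: list[str]) -> "ExclusionFlags":
        return cls(excluded=bool(reasons), reasons=tuple(reasons))


def _cut(trial: TrialRecord, pre_s: float, post_total_s: float, force: SampledTrace | None) -> list[ResponseSegment]:
    if trial.onsets_s is None or len(trial.onsets_s) == 0:
        raise SegmentationError(
            f"trial {trial.key} has no target onsets in metadata; "
            "segmentation never infers onsets from the force signal"
        )
    src_force = force if force is not None else trial.force
    if src_force.n != trial.target.n or src_force.sample_rate_hz != trial.sample_rate_hz:
        raise SegmentationError("force trace does not match the trial's target grid")
    on_s = trial.on_duration_s
    if on_s is None:
        raise SegmentationError(f"trial {trial.key} lacks on_duration_s metadata")

    t_lo = trial.target.t0_s
    t_hi = t_lo + trial.target.duration_s
    usable = [
        onset for onset in trial.onsets_s
        if onset - pre_s >= t_lo - _EDGE and onset + post_total_s <= t_hi + _EDGE
    ]
    if len(usable) < len(trial.onsets_s):
        raise SegmentationError(
            f"only {len(usable)} of {len(trial.onsets_s)} response windows fit the "
            f"trace; onsets found: {[round(o, 3) for o in usable]}"
        )

    upper = float(trial.target.values.max())
    baseline = float(trial.target.values.min())
    step_size = upper - baseline

    segments = []
    for k, onset in enumerate(usable):
        a, b = onset - pre_s, onset + post_total_s
        segments.append(
            ResponseSegment(
                participant_id=trial.participant_id,
                condition=trial.condition,
                task=trial.task,
                repetition=trial.repetition,
                step_index=k,
                window_trial_s=(a, b),
                onset_trial_s=onset,
                onset_seg_s=pre_s,
                stepdown_seg_s=pre_s + on_s,
                baseline_bw=baseline,
                step_size_bw=step_size,
                force=src_force.crop(a, b, rebase=True),
                target=trial.target.crop(a, b, rebase=True),
            )
        )
    return segments


def segment_step_task(trial: TrialRecord, force: SampledTrace | None = None) -> list[ResponseSegment]:
    """Cut a step trial into one 6-s segment per target step.

    ``force`` optionally substitutes a preprocessed (filtered) force trace
    on the same grid.  Deterministic: identical inputs give identical
    windows.
    """
    if trial.task is not Task.STEP:
        raise SegmentationError(f"expected a STEP trial, got {trial.task.value}")
    pre, post = STEP_MARGINS_S
    on_s = trial.on_duration_s if trial.on_duration_s is not None else 4.0
    return _cut(trial, pre, on_s + post, force)


def segment_pulse_task(trial: TrialRecord, force: SampledTrace | None = None) -> list[ResponseSegment]:
    """Cut a pulse trial into one 3-s segment per pulse."""
    if trial.task is not Task.PULSE:
        raise SegmentationError(f"expected a PULSE trial, got {trial.task.value}")
    return _cut(trial, PULSE_MARGIN_S, PULSE_MARGIN_S, force)


# ---------------------------------------------------------------------------
# Exclusion criteria
# ---------------------------------------------------------------------------


def _mean_in(trace: SampledTrace, t_start: float, t_end: float) -> float:
    vals = window_values_closed(trace, t_start, t_end)
    return float(vals.mean()) if vals.size else np.nan


def _resolve(config: AnalysisConfig | ExclusionConfig | None) -> ExclusionConfig:
    if config is None:
        return ExclusionConfig()
    if isinstance(config, AnalysisConfig):
        return config.exclusion
    return config


def _step_up_time(
    segment: ResponseSegment, threshold_frac: float, anchor_frac: float, t_limit: float
) -> float | None:
    """When the response "stepped up": the last crossing of the low
    threshold that precedes the half-rise point, i.e. the crossing connected
    to the actual rise rather than a transient noise excursion.

    Returns ``None`` when the response never reaches the half-rise level
    before the target steps down.  A force already above the threshold from
    the very start of the segment "stepped up" at the segment start.
    """
    thr = segment.baseline_bw + threshold_frac * segment.step_size_bw
    anchor = segment.baseline_bw + anchor_frac * segment.step_size_bw
    t0 = segment.force.t0_s
    t_half = first_crossing(segment.force, anchor, t0, t_limit + _EDGE, "up")
    if t_half is None:
        return None
    t_up = last_crossing_at_or_before(segment.force, thr, t_half, "up")
    return t0 if t_up is None else t_up


def apply_step_exclusions(
    segment: ResponseSegment, config: AnalysisConfig | ExclusionConfig | None = None
) -> ExclusionFlags:
    """Screen a 6-s step segment against the four step criteria.

    1. ``early_rise`` -- the response stepped up at/before 0.5 s pre-onset;
    2. ``no_rise`` -- it did not step up within 0.5 s after the onset;
    3. ``elevated_baseline`` -- mean force above threshold over the 0.5 s
       leading up to the step-up;
    4. ``early_fall`` -- mean force below threshold over the last 1 s of the
       on-phase (the response stepped down >= 1 s before the target).

    A sustained early rise necessarily elevates the pre-onset mean, so
    ``early_rise`` implies ``elevated_baseline``.
    """
    cfg = _resolve(config)
    thr = segment.baseline_bw + cfg.baseline_frac * segment.step_size_bw
    onset = segment.onset_seg_s
    stepdown = segment.stepdown_seg_s
    t_up = _step_up_time(segment, cfg.baseline_frac, cfg.rise_anchor_frac, stepdown)
    if cfg.no_rise_frac == cfg.baseline_frac:
        t_up_nr = t_up
    else:
        t_up_nr = _step_up_time(segment, cfg.no_rise_frac, cfg.rise_anchor_frac, stepdown)
    reasons = []
    if t_up is not None and t_up <= onset - cfg.pre_window_s + _EDGE:
        reasons.append("early_rise")
    if t_up_nr is None or t_up_nr > onset + cfg.post_window_s + _EDGE:
        reasons.append("no_rise")
    if _mean_in(segment.force, onset - cfg.pre_window_s, onset) > thr:
        reasons.append("elevated_baseline")
    if _mean_in(segment.force, stepdown - cfg.early_fall_s, stepdown) < thr:
        reasons.append("early_fall")
    return ExclusionFlags.from_reasons(reasons)


def apply_pulse_exclusions(
    segment: ResponseSegment, config: AnalysisConfig | ExclusionConfig | None = None
) -> ExclusionFlags:
    """Screen a 3-s pulse segment.

    1. ``early_rise`` -- the response stepped up at/before 0.25 s pre-onset;
    2. ``late_fall`` -- after rising, its descent (first drop below the 90%
       level) did not begin until more than 0.5 s after the pulse stepped
       down.  Descent *onset* is the criterion: requiring the fall to
       complete within the window would reject ordinary responses whose
       90-10% fall takes a few hundred ms.
    """
    cfg = _resolve(config)
    fall_level = segment.baseline_bw + cfg.pulse_fall_frac * segment.step_size_bw
    t0 = segment.force.t0_s
    t_end = t0 + segment.force.duration_s
    reasons = []
    t_up = _step_up_time(segment, cfg.baseline_frac, cfg.rise_anchor_frac, t_end)
    if t_up is not None and t_up <= segment.onset_seg_s - cfg.pulse_pre_s + _EDGE:
        reasons.append("early_rise")
    # descent onset connected to the response: first drop below the fall
    # level after it was reached; exactly at stepdown + 0.5 s is timely.
    # A response that never reached the fall level has no descent to be
    # late -- it is a weak response, not a held one.
    t_top = first_crossing(segment.force, fall_level, t0, t_end, "up")
    if t_top is not None:
        t_down = first_crossing(segment.force, fall_level, t_top, t_end, "down")
        if t_down is None or t_down > segment.stepdown_seg_s + cfg.pulse_post_s + _EDGE:
            reasons.append("late_fall")
    return ExclusionFlags.from_reasons(reasons)
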