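"""Response characteristics and fatigue measures.

Step/pulse responsiveness and accuracy are the canonical second-order
descriptors: 10-90% rise time (ms), bandwidth = 0.35 / rise time (Hz),
90-10% fall time (ms), overshoot (% of step size, signed), steady-state
error (% of target) and steady-state variability (CV %) over the settled
2-4 s after the step-up.  Whole-trial measures: MVC mean force over 4-8 s,
and hold-task variability as CV % per 1-s segment after the first 5 s.

Threshold crossings are located by linear interpolation between samples
(first-crossing rule), which makes the timing metrics deterministic and
robust to the sampling grid.  All analysis windows are half-open
``[start, end)`` on the segment clock, so shifting a segment's time origin
leaves every metric unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, MetricsConfig
from .events import crossing_times, first_crossing, window_values
from .segment import ResponseSegment
from .trace import SampledTrace, Task, TrialRecord

__all__ = [
    "StepMetrics",
    "HoldMetrics",
    "MVCMetrics",
    "crossing_times",
    "first_crossing",
    "rise_time",
    "bandwidth",
    "fall_time",
    "overshoot",
    "steady_state_error",
    "steady_state_variability",
    "compute_step_metrics",
    "mvc_mean",
    "hold_variability",
]

#: Rise time (s) times bandwidth (Hz) -- the first-order-system constant.
BANDWIDTH_CONSTANT = 0.35


# ---------------------------------------------------------------------------
# Step / pulse response characteristics
# ---------------------------------------------------------------------------


@dataclass
class StepMetrics:
    """The six response characteristics for one segment.

    Uncomputable metrics are NaN with ``flags[name] = False``.  Whenever a
    rise time exists, ``bandwidth_hz * rise_time_ms / 1000 == 0.35`` exactly.
    """

    rise_time_ms: float = math.nan
    bandwidth_hz: float = math.nan
    fall_time_ms: float = math.nan
    overshoot_pct: float = math.nan
    steady_state_error_pct: float = math.nan
    steady_state_variability_pct: float = math.nan
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rise_time_ms": self.rise_time_ms,
            "bandwidth_hz": self.bandwidth_hz,
            "fall_time_ms": self.fall_time_ms,
            "overshoot_pct": self.overshoot_pct,
            "steady_state_error_pct": self.steady_state_error_pct,
            "steady_state_variability_pct": self.steady_state_variability_pct,
        }


def _cfg(config: AnalysisConfig | MetricsConfig | None) -> MetricsConfig:
    if config is None:
        return MetricsConfig()
    if isinstance(config, AnalysisConfig):
        return config.metrics
    return config


def rise_time(segment: ResponseSegment, config: AnalysisConfig | MetricsConfig | None = None) -> float | None:
    """10-90% rise time in ms, searched in [onset - 0.5 s, onset + 1 s)."""
    cfg = _cfg(config)
    thr_lo = segment.baseline_bw + cfg.rise_frac_lo * segment.step_size_bw
    thr_hi = segment.baseline_bw + cfg.rise_frac_hi * segment.step_size_bw
    a = segment.onset_seg_s + cfg.rise_window_s[0]
    b = segment.onset_seg_s + cfg.rise_window_s[1]
    t_lo = first_crossing(segment.force, thr_lo, a, b, "up")
    if t_lo is None:
        return None
    t_hi = first_crossing(segment.force, thr_hi, t_lo, b, "up")
    if t_hi is None:
        return None
    return (t_hi - t_lo) * 1000.0


def bandwidth(rise_time_ms: float | None) -> float | None:
    """0.35 divided by the rise time in seconds."""
    if rise_time_ms is None or not rise_time_ms > 0 or not math.isfinite(rise_time_ms):
        return None
    return BANDWIDTH_CONSTANT / (rise_time_ms / 1000.0)


def fall_time(segment: ResponseSegment, config: AnalysisConfig | MetricsConfig | None = None) -> float | None:
    """90-10% fall time in ms around the target step-down.

    STEP segments search segment seconds [4, 6); pulse segments search from
    the pulse end to the segment end.
    """
    cfg = _cfg(config)
    thr_lo = segment.baseline_bw + cfg.rise_frac_lo * segment.step_size_bw
    thr_hi = segment.baseline_bw + cfg.rise_frac_hi * segment.step_size_bw
    t0 = segment.force.t0_s
    if segment.task is Task.STEP:
        a, b = t0 + cfg.fall_window_s[0], t0 + cfg.fall_window_s[1]
    else:
        a, b = segment.stepdown_seg_s, t0 + segment.force.duration_s
    t_hi = first_crossing(segment.force, thr_hi, a, b, "down")
    if t_hi is None:
        return None
    t_lo = first_crossing(segment.force, thr_lo, t_hi, b, "down")
    if t_lo is None:
        return None
    return (t_lo - t_hi) * 1000.0


def overshoot(segment: ResponseSegment, config: AnalysisConfig | MetricsConfig | None = None) -> float | None:
    """Peak excursion above the upper target as % of step size (signed)."""
    cfg = _cfg(config)
    a = segment.onset_seg_s + cfg.rise_window_s[0]
    b = segment.onset_seg_s + cfg.rise_window_s[1]
    vals = window_values(segment.force, a, b)
    if vals.size == 0:
        return None
    upper = segment.baseline_bw + segment.step_size_bw
    return 100.0 * (float(vals.max()) - upper) / segment.step_size_bw


def steady_state_error(segment: ResponseSegment, config: AnalysisConfig | MetricsConfig | None = None) -> float | None:
    """|mean force - target| during onset + [2, 4) s, as % of the target."""
    cfg = _cfg(config)
    a = segment.onset_seg_s + cfg.ss_window_s[0]
    b = segment.onset_seg_s + cfg.ss_window_s[1]
    vals = window_values(segment.force, a, b)
    if vals.size == 0:
        return None
    upper = segment.baseline_bw + segment.step_size_bw
    return 100.0 * abs(float(vals.mean()) - upper) / upper


def steady_state_variability(segment: ResponseSegment, config: AnalysisConfig | MetricsConfig | None = None) -> float | None:
    """CV % of the force during onset + [2, 4) s."""
    cfg = _cfg(config)
    a = segment.onset_seg_s + cfg.ss_window_s[0]
    b = segment.onset_seg_s + cfg.ss_window_s[1]
    vals = window_values(segment.force, a, b)
    if vals.size == 0:
        return None
    mean = float(vals.mean())
    if mean == 0:
        return None
    return 100.0 * float(vals.std(ddof=0)) / mean


def compute_step_metrics(
    segment: ResponseSegment, config: AnalysisConfig | MetricsConfig | None = None
) -> StepMetrics:
    """All response characteristics for one segment.

    Pulse segments carry only the responsiveness set (rise, bandwidth,
    fall); the accuracy metrics require a sustained on-phase.
    """
    out = StepMetrics()
    rt = rise_time(segment, config)
    bw = bandwidth(rt)
    ft = fall_time(segment, config)
    out.rise_time_ms = math.nan if rt is None else rt
    out.bandwidth_hz = math.nan if bw is None else bw
    out.fall_time_ms = math.nan if ft is None else ft
    out.flags = {"rise_time_ms": rt is not None, "bandwidth_hz": bw is not None,
                 "fall_time_ms": ft is not None}
    if segment.task is Task.STEP:
        ov = overshoot(segment, config)
        se = steady_state_error(segment, config)
        sv = steady_state_variability(segment, config)
        out.overshoot_pct = math.nan if ov is None else ov
        out.steady_state_error_pct = math.nan if se is None else se
        out.steady_state_variability_pct = math.nan if sv is None else sv
        out.flags.update({"overshoot_pct": ov is not None,
                          "steady_state_error_pct": se is not None,
                          "steady_state_variability_pct": sv is not None})
    else:
        out.flags.update({"overshoot_pct": False, "steady_state_error_pct": False,
                          "steady_state_variability_pct": False})
    return out


# ---------------------------------------------------------------------------
# Whole-trial fatigue measures
# ---------------------------------------------------------------------------


@dataclass
class MVCMetrics:
    mean_force_bw: float


@dataclass
class HoldMetrics:
    """Per-second force variability through a hold.

    ``cv_per_second_pct[k]`` is the CV % of the 1-s segment starting at
    ``skip + k`` seconds; ``final10_mean_cv_pct`` averages the last 10
    segments (all available if fewer, with ``short=True``).
    """

    cv_per_second_pct: np.ndarray
    segment_start_s: np.ndarray
    final10_mean_cv_pct: float
    short: bool = False


def mvc_mean(
    trial: TrialRecord | SampledTrace, config: AnalysisConfig | MetricsConfig | None = None
) -> MVCMetrics | None:
    """Mean force over the mid-trial 4-8 s window of an MVC trial."""
    cfg = _cfg(config)
    trace = trial.force if isinstance(trial, TrialRecord) else trial
    a, b = cfg.mvc_window_s
    if trace.duration_s + 1e-9 < b:
        return None
    vals = window_values(trace, trace.t0_s + a, trace.t0_s + b)
    return MVCMetrics(mean_force_bw=float(vals.mean()))


def hold_variability(
    trial: TrialRecord | SampledTrace, config: AnalysisConfig | MetricsConfig | None = None
) -> HoldMetrics | None:
    """CV % per 1-s segment of a hold, skipping the first 5 s.

    A 73-s hold yields 68 segments; trials shorter than 15 s are
    uncomputable (``None``).  Partial trailing segments are dropped.
    """
    cfg = _cfg(config)
    trace = trial.force if isinstance(trial, TrialRecord) else trial
    if trace.duration_s < 15.0:
        return None
    n_seg = int(math.floor((trace.duration_s - cfg.hold_skip_s) / cfg.hold_segment_s + 1e-9))
    m = int(round(cfg.hold_segment_s * trace.sample_rate_hz))
    i0 = int(round(cfg.hold_skip_s * trace.sample_rate_hz))
    chunks = trace.values[i0:i0 + n_seg * m].reshape(n_seg, m)
    means = chunks.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means == 0, np.nan, 100.0 * chunks.std(axis=1, ddof=0) / means)
    starts = cfg.hold_skip_s + cfg.hold_segment_s * np.arange(n_seg)
    n_final = min(cfg.hold_final_n, n_seg)
    final10 = float(np.nanmean(cvs[-n_final:]))
    return HoldMetrics(
        cv_per_second_pct=cvs,
        segment_start_s=starts,
        final10_mean_cv_pct=final10,
        short=n_seg < cfg.hold_final_n,
    )
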