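"""Threshold-crossing and windowing primitives shared by segmentation and
metrics.

All routines treat a trace as a continuous piecewise-linear signal: crossing
instants are interpolated between the bracketing samples, and analysis
windows are half-open ``[start, end)`` on the trace's own clock (closed
variants exist for the exclusion screen, whose windows include their edges).
"""

from __future__ import annotations

import numpy as np

from .trace import SampledTrace

__all__ = [
    "crossing_times",
    "first_crossing",
    "last_crossing_at_or_before",
    "window_slice",
    "window_values",
    "window_values_closed",
]

_EDGE = 1e-9


def crossing_times(trace: SampledTrace, level: float, direction: str = "up") -> np.ndarray:
    """All interpolated times at which the trace crosses ``level``.

    An "up" crossing is a sample below the level followed by one at or above
    it; "down" is the mirror image.
    """
    y = trace.values
    s = y - level
    if direction == "up":
        idx = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
    elif direction == "down":
        idx = np.flatnonzero((s[:-1] > 0) & (s[1:] <= 0))
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if idx.size == 0:
        return np.empty(0)
    frac = (level - y[idx]) / (y[idx + 1] - y[idx])
    return trace.t0_s + (idx + frac) * trace.dt


def first_crossing(
    trace: SampledTrace,
    level: float,
    t_start: float,
    t_end: float,
    direction: str = "up",
) -> float | None:
    """First crossing of ``level`` inside ``[t_start, t_end)``, or ``None``."""
    tc = crossing_times(trace, level, direction)
    tc = tc[(tc >= t_start) & (tc < t_end)]
    return float(tc[0]) if tc.size else None


def last_crossing_at_or_before(
    trace: SampledTrace, level: float, t_limit: float, direction: str = "up"
) -> float | None:
    """Latest crossing of ``level`` at or before ``t_limit``, or ``None``."""
    tc = crossing_times(trace, level, direction)
    tc = tc[tc <= t_limit + _EDGE]
    return float(tc[-1]) if tc.size else None


def window_slice(trace: SampledTrace, t_start: float, t_end: float, *, closed: bool = False) -> slice:
    """Sample-index slice of the window (half-open, or closed at both ends)."""
    fs = trace.sample_rate_hz
    i0 = int(np.ceil((t_start - trace.t0_s) * fs - _EDGE * fs))
    if closed:
        i1 = int(np.floor((t_end - trace.t0_s) * fs + _EDGE * fs)) + 1
    else:
        i1 = int(np.ceil((t_end - trace.t0_s) * fs - _EDGE * fs))
    return slice(max(i0, 0), min(max(i1, 0), trace.n))


def window_values(trace: SampledTrace, t_start: float, t_end: float) -> np.ndarray:
    """Samples with time in ``[t_start, t_end)``."""
    return trace.values[window_slice(trace, t_start, t_end)]


def window_values_closed(trace: SampledTrace, t_start: float, t_end: float) -> np.ndarray:
    """Samples with time in the closed interval ``[t_start, t_end]``."""
    return trace.values[window_slice(trace, t_start, t_end, closed=True)]
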