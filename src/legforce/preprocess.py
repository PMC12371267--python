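"""Signal conditioning: Butterworth filtering and EMG clock alignment.

Force is low-passed at 10 Hz (4th order) before any metric is computed --
this is the signal the participants saw and controlled.  Zero-lag filters
run forward-backward (``sosfiltfilt``), which squares the magnitude response
and cancels phase; segments are padded by reflection over roughly one filter
settling length so no transient leaks into the first analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import EMGFilterConfig, ForceFilterConfig
from .trace import EMGChannelSet, SampledTrace

__all__ = ["FilterSpec", "filter_force", "filter_emg", "correct_sensor_delay"]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter stage.

    ``order`` is the design order of one pass; a zero-lag (forward-backward)
    application squares the magnitude response.
    """

    kind: str                       # lowpass | highpass | bandpass | bandstop
    order: int
    cutoffs_hz: tuple[float, ...]
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass", "bandstop"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError(f"filter order must be >= 1, got {self.order}")
        n_expected = 2 if self.kind in ("bandpass", "bandstop") else 1
        if len(self.cutoffs_hz) != n_expected:
            raise ValueError(
                f"{self.kind} filter needs {n_expected} cutoff(s), got {self.cutoffs_hz}"
            )
        if any(c <= 0 for c in self.cutoffs_hz):
            raise ValueError(f"cutoffs must be > 0, got {self.cutoffs_hz}")

    def sos(self, sample_rate_hz: float) -> np.ndarray:
        nyq = sample_rate_hz / 2.0
        if max(self.cutoffs_hz) >= nyq:
            raise ValueError(
                f"cutoff {max(self.cutoffs_hz)} Hz >= Nyquist {nyq} Hz "
                f"at {sample_rate_hz} Hz sampling"
            )
        wn = self.cutoffs_hz[0] if len(self.cutoffs_hz) == 1 else list(self.cutoffs_hz)
        # scipy's N doubles for band filters; keep `order` = overall design order.
        n = self.order if len(self.cutoffs_hz) == 1 else max(1, self.order // 2)
        return signal.butter(n, wn, btype=self.kind, fs=sample_rate_hz, output="sos")


def _apply(spec: FilterSpec, trace: SampledTrace) -> SampledTrace:
    sos = spec.sos(trace.sample_rate_hz)
    x = trace.values
    if spec.zero_lag:
        # Reflective padding over ~one settling length of the slowest pole.
        f_low = min(spec.cutoffs_hz)
        padlen = int(min(x.size - 1, max(24, round(trace.sample_rate_hz / f_low))))
        y = signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)
    else:
        zi = signal.sosfilt_zi(sos) * x[0]
        y, _ = signal.sosfilt(sos, x, zi=zi)
    return trace.with_values(y)


def filter_force(
    trace: SampledTrace, spec: FilterSpec | None = None, config: ForceFilterConfig | None = None
) -> SampledTrace:
    """Low-pass the force signal (default: 10 Hz, order 4, zero-lag)."""
    if spec is None:
        cfg = config or ForceFilterConfig()
        if not cfg.enabled:
            return trace
        spec = FilterSpec("lowpass", cfg.order, (cfg.cutoff_hz,), cfg.zero_lag)
    return _apply(spec, trace)


def filter_emg(
    emg: EMGChannelSet,
    config: EMGFilterConfig | None = None,
    *,
    allow_any_rate: bool = False,
) -> EMGChannelSet:
    """Band-pass 30-400 Hz then band-stop 59-61 Hz, both zero-lag order 4."""
    cfg = config or EMGFilterConfig()
    if emg.sample_rate_hz != cfg.expected_rate_hz and not allow_any_rate:
        raise ValueError(
            f"EMG sampled at {emg.sample_rate_hz} Hz, expected {cfg.expected_rate_hz} Hz "
            "(pass allow_any_rate=True to override)"
        )
    bp = FilterSpec("bandpass", cfg.order, cfg.band_hz, cfg.zero_lag)
    bs = FilterSpec("bandstop", cfg.order, cfg.bandstop_hz, cfg.zero_lag)
    return emg.map(lambda tr: _apply(bs, _apply(bp, tr)))


def correct_sensor_delay(
    emg: EMGChannelSet, delay_s: float | dict[str, float] = 500e-6
) -> EMGChannelSet:
    """Shift channels onto the force-plate clock, undoing transmission delay.

    A recorded sample at time ``t`` was produced at ``t - delay``; correction
    advances each channel by its delay.  Integer-sample delays shift exactly;
    fractional delays interpolate linearly.  Length is preserved (trailing
    edge repeats the final sample).
    """

    def shift(tr: SampledTrace, d: float) -> SampledTrace:
        if d == 0:
            return tr
        if d < 0 or d >= tr.duration_s:
            raise ValueError(f"delay {d} s outside [0, {tr.duration_s}) s")
        k = d * tr.sample_rate_hz
        x = tr.values
        if abs(k - round(k)) < 1e-9:
            k = int(round(k))
            y = np.concatenate([x[k:], np.full(k, x[-1])])
        else:
            idx = np.arange(x.size) + k
            y = np.interp(idx, np.arange(x.size), x, right=x[-1])
        return tr.with_values(y)

    if isinstance(delay_s, dict):
        missing = set(emg.names) - set(delay_s)
        if missing:
            raise ValueError(f"no delay given for channel(s): {sorted(missing)}")
        return EMGChannelSet({n: shift(emg[n], delay_s[n]) for n in emg.names})
    return emg.map(lambda tr: shift(tr, float(delay_s)))
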