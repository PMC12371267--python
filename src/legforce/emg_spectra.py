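"""EMG median frequency: the spectral fatigue index.

The median frequency (MDF) of a surface-EMG segment is the frequency that
splits the power spectrum, band-limited to 30-400 Hz, into equal halves;
it drifts downward as a muscle fatigues.  The pipeline estimates a
single-taper periodogram per non-overlapping 2-s segment (0.5 Hz bins at
2000 Hz) and interpolates the half-power point linearly between bins; Welch
averaging is available behind the ``emg.estimator`` config switch.  Fatigue
is summarized per muscle as the percent drop from the first 10 s of the
initial hold to the final 10 s of the last hold of a fatigue condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig, EMGSpectraConfig
from .trace import SampledTrace

__all__ = ["SpectralSeries", "median_frequency", "mdf_time_series", "mdf_fatigue_change"]


@dataclass
class SpectralSeries:
    """Median frequency per 2-s segment of one channel."""

    times_s: np.ndarray  # segment centers, trace clock
    mdf_hz: np.ndarray
    channel: str = ""

    @property
    def n(self) -> int:
        return self.mdf_hz.size


def _resolve(config: AnalysisConfig | EMGSpectraConfig | None) -> EMGSpectraConfig:
    if config is None:
        return EMGSpectraConfig()
    if isinstance(config, AnalysisConfig):
        return config.emg
    return config


def median_frequency(
    segment: SampledTrace | np.ndarray,
    sample_rate_hz: float | None = None,
    config: AnalysisConfig | EMGSpectraConfig | None = None,
) -> float | None:
    """Median frequency (Hz) of one EMG segment within the analysis band.

    Power below the returned frequency equals half the total band power;
    the half-power point is interpolated linearly along the cumulative
    periodogram.  All-zero segments are uncomputable (``None``).
    """
    cfg = _resolve(config)
    if isinstance(segment, SampledTrace):
        x, fs = segment.values, segment.sample_rate_hz
    else:
        if sample_rate_hz is None:
            raise ValueError("sample_rate_hz required when passing a bare array")
        x, fs = np.asarray(segment, dtype=float), float(sample_rate_hz)
    if not np.any(x):
        return None
    if cfg.estimator == "welch":
        freqs, power = sps.welch(x, fs=fs, nperseg=min(x.size, int(fs)))
    else:
        # boxcar periodogram via the FFT directly; only power *ratios*
        # matter for the median, so the one-sided scaling is irrelevant
        spectrum = np.fft.rfft(x)
        power = np.abs(spectrum) ** 2
        freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    band = (freqs >= cfg.band_hz[0]) & (freqs <= cfg.band_hz[1])
    freqs, power = freqs[band], power[band]
    total = power.sum()
    if total <= 0:
        return None
    cum = np.cumsum(power)
    half = total / 2.0
    rel = 1e-9 * total
    i = int(np.searchsorted(cum, half - rel))
    if abs(cum[i] - half) <= rel:
        # cumulative power hits exactly half at this bin: the median sits
        # midway to the bin where it first exceeds half (two equal lines at
        # 80 and 120 Hz -> 100 Hz)
        j = int(np.searchsorted(cum, half + rel, side="right"))
        j = min(j, freqs.size - 1)
        return float((freqs[i] + freqs[j]) / 2.0)
    if i == 0:
        return float(freqs[0])
    # linear interpolation of the cumulative power between adjacent bins
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(freqs[i - 1] + frac * (freqs[i] - freqs[i - 1]))


def mdf_time_series(
    channel: SampledTrace,
    config: AnalysisConfig | EMGSpectraConfig | None = None,
    *,
    name: str = "",
) -> SpectralSeries:
    """MDF per non-overlapping 2-s segment along a filtered channel.

    A 73-s hold yields 36 segments; a trace shorter than one window yields
    an empty series.
    """
    cfg = _resolve(config)
    n_win = int(round(cfg.window_s * channel.sample_rate_hz))
    n_seg = channel.n // n_win
    times = np.empty(n_seg)
    mdf = np.empty(n_seg)
    for k in range(n_seg):
        chunk = channel.values[k * n_win:(k + 1) * n_win]
        val = median_frequency(chunk, channel.sample_rate_hz, cfg)
        mdf[k] = np.nan if val is None else val
        times[k] = channel.t0_s + (k + 0.5) * cfg.window_s
    return SpectralSeries(times_s=times, mdf_hz=mdf, channel=name)


def mdf_fatigue_change(
    baseline_series: SpectralSeries,
    final_series: SpectralSeries,
    config: AnalysisConfig | EMGSpectraConfig | None = None,
) -> float | None:
    """Percent MDF reduction from baseline start to fatigued end.

    Compares the mean over the baseline series' first 10 s (5 two-second
    segments) against the mean over the final series' last 10 s, as a
    percentage of the baseline mean.  Positive values mean the spectrum
    compressed (fatigue).  ``None`` when either series is too short.
    """
    cfg = _resolve(config)
    k = max(1, int(round(cfg.baseline_window_s / cfg.window_s)))
    if baseline_series.n < k or final_series.n < k:
        return None
    base = float(np.nanmean(baseline_series.mdf_hz[:k]))
    final = float(np.nanmean(final_series.mdf_hz[-k:]))
    if not np.isfinite(base) or base == 0:
        return None
    return 100.0 * (base - final) / base
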