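"""Core data carriers for the pipeline.

Everything downstream exchanges uniformly sampled scalar time series
(:class:`SampledTrace`), optionally bundled with six-channel surface EMG
(:class:`EMGChannelSet`) into one task execution (:class:`TrialRecord`).
Forces are carried in body weights (BW); 1.0 BW is the participant's
standing weight.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Condition",
    "Task",
    "MUSCLES",
    "SampledTrace",
    "EMGChannelSet",
    "TrialRecord",
]


class Condition(str, enum.Enum):
    """Protocol conditions, in session order."""

    TRAINING = "Training"
    PRE_FATIGUE = "PreFatigue"
    FATIGUE_1 = "Fatigue1"
    FATIGUE_2 = "Fatigue2"
    FATIGUE_3 = "Fatigue3"

    @classmethod
    def ordered(cls) -> tuple["Condition", ...]:
        return tuple(cls)


class Task(str, enum.Enum):
    MVC = "MVC"
    HOLD = "HOLD"
    STEP = "STEP"
    PULSE = "PULSE"


#: The six recorded right-leg muscles, in fixed column order.
MUSCLES: tuple[str, ...] = (
    "vastus_medialis",
    "vastus_lateralis",
    "rectus_femoris",
    "biceps_femoris",
    "gastroc_medialis",
    "gastroc_lateralis",
)


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values
        Sample values (finite, 1-D).
    sample_rate_hz
        Sampling rate in Hz, > 0.
    t0_s
        Time of the first sample, seconds.
    """

    values: np.ndarray
    sample_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError(f"trace values must be 1-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.sample_rate_hz

    def index_at(self, t_s: float) -> int:
        """Sample index of time ``t_s`` (rounded to the nearest sample)."""
        return int(round((t_s - self.t0_s) * self.sample_rate_hz))

    def crop(self, t_start_s: float, t_end_s: float, *, rebase: bool = False) -> "SampledTrace":
        """Excerpt covering the half-open interval ``[t_start_s, t_end_s)``.

        With ``rebase=True`` the excerpt's clock restarts at 0.
        """
        i0 = self.index_at(t_start_s)
        i1 = self.index_at(t_end_s)
        if i0 < 0 or i1 > self.n or i1 <= i0:
            raise ValueError(
                f"crop [{t_start_s}, {t_end_s}) s outside trace "
                f"[{self.t0_s}, {self.t0_s + self.duration_s}) s"
            )
        t0 = 0.0 if rebase else self.t0_s + i0 / self.sample_rate_hz
        return SampledTrace(self.values[i0:i1].copy(), self.sample_rate_hz, t0)

    def with_values(self, values: np.ndarray) -> "SampledTrace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class EMGChannelSet:
    """Six named surface-EMG channels sharing one clock (default 2000 Hz)."""

    channels: Mapping[str, SampledTrace]

    def __post_init__(self) -> None:
        chans = dict(self.channels)
        if not chans:
            raise ValueError("EMGChannelSet needs at least one channel")
        lengths = {tr.n for tr in chans.values()}
        rates = {tr.sample_rate_hz for tr in chans.values()}
        if len(lengths) != 1:
            raise ValueError(f"EMG channels differ in length: {sorted(lengths)}")
        if len(rates) != 1:
            raise ValueError(f"EMG channels differ in sample rate: {sorted(rates)}")
        object.__setattr__(self, "channels", chans)

    @property
    def sample_rate_hz(self) -> float:
        return next(iter(self.channels.values())).sample_rate_hz

    @property
    def n(self) -> int:
        return next(iter(self.channels.values())).n

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> SampledTrace:
        return self.channels[name]

    def map(self, fn) -> "EMGChannelSet":
        """Apply ``fn(SampledTrace) -> SampledTrace`` to every channel."""
        return EMGChannelSet({name: fn(tr) for name, tr in self.channels.items()})


@dataclass
class TrialRecord:
    """One task execution: force + target traces plus protocol metadata.

    Force and target are stored in BW and share sample rate and length.
    ``onsets_s`` carries the target step-up times (trial clock); segmentation
    anchors to these, never to the force signal.
    """

    participant_id: str
    condition: Condition
    task: Task
    repetition: int
    body_weight_n: float
    force: SampledTrace
    target: SampledTrace
    emg: EMGChannelSet | None = None
    onsets_s: tuple[float, ...] | None = None
    on_duration_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.task = Task(self.task)
        if not self.body_weight_n > 0:
            raise ValueError(f"body_weight_n must be > 0, got {self.body_weight_n}")
        if self.force.n != self.target.n:
            raise ValueError(
                f"force ({self.force.n}) and target ({self.target.n}) lengths differ"
            )
        if self.force.sample_rate_hz != self.target.sample_rate_hz:
            raise ValueError("force and target sample rates differ")

    @property
    def sample_rate_hz(self) -> float:
        return self.force.sample_rate_hz

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.participant_id, self.condition.value, self.task.value, self.repetition)
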