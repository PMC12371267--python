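"""Synthetic force and EMG sessions with programmable fatigue.

The generator emulates a single-leg force-matching study: a participant
stands on one leg on a force plate and matches visual targets in body-weight
(BW) units.  Four task types are produced:

* **MVC** -- 10 s maximal push toward an unattainable 5 BW target;
* **Hold** -- 73 s sustained match of 1 BW + 25% of the pre-fatigue MVC
  (the fatiguing task);
* **Step** -- 10 square steps 1.0 -> 1.4 BW, 4 s on / 3 s off, 73 s;
* **Pulse** -- 10 brief 0.05 s excursions to 1.4 BW over 73 s.

The simulated "participant" is a pure motor delay followed by a linear
second-order plant: its two parameters map one-to-one onto the rise time and
overshoot that the analysis measures.  Variability is signal-dependent
band-limited Gaussian noise whose SD tracks the active force above passive
standing support, so a programmed noise multiplier scales the measured
coefficient of variation one-to-one.  Surface EMG is band-shaped noise
amplitude-modulated
by the force; muscle fatigue compresses its spectrum multiplicatively.

Fatigue across the five protocol conditions (Training, PreFatigue,
Fatigue1-3) is programmed as per-condition multipliers on maximal force,
response time constant, noise level, and EMG spectral position.  The default
profile reproduces the effect magnitudes the analysis is designed to detect:
a 26.1% MVC decline, 23.3% rise-time slowing, 4.6-fold hold-variability
growth, and ~10% median-frequency compression by the final condition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
from scipy import signal as sps

from .trace import MUSCLES, Condition, EMGChannelSet, SampledTrace, Task, TrialRecord

__all__ = [
    "TaskSpec",
    "PlantParams",
    "ConditionEffects",
    "FatigueProfile",
    "EMGParams",
    "make_target_waveform",
    "simulate_force_response",
    "simulate_emg",
    "simulate_trial",
    "simulate_session",
    "default_plant",
    "default_profile",
    "default_emg_params",
]

# ---------------------------------------------------------------------------
# Task specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """Geometry of one target waveform."""

    kind: Task
    baseline_bw: float = 1.0
    step_size_bw: float = 0.4
    n_reps: int = 10
    on_duration_s: float = 4.0
    off_duration_s: float = 3.0
    lead_in_s: float = 3.0
    total_duration_s: float = 73.0
    mvc_target_bw: float = 5.0
    hold_level_bw: float | None = None
    sample_rate_hz: float = 1000.0

    def validate(self) -> "TaskSpec":
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.baseline_bw <= 0:
            raise ValueError(f"baseline_bw must be > 0, got {self.baseline_bw}")
        if self.kind in (Task.STEP, Task.PULSE):
            if self.step_size_bw <= 0:
                raise ValueError(f"step_size_bw must be > 0, got {self.step_size_bw}")
            if self.n_reps < 0:
                raise ValueError(f"n_reps must be >= 0, got {self.n_reps}")
            need = self.lead_in_s + self.n_reps * (self.on_duration_s + self.off_duration_s)
            if need > self.total_duration_s + 1e-9:
                raise ValueError(
                    f"n_reps x (on+off) + lead-in = {need:.2f} s exceeds "
                    f"total_duration_s = {self.total_duration_s} s"
                )
        if self.kind is Task.MVC and self.mvc_target_bw <= 0:
            raise ValueError(f"mvc_target_bw must be > 0, got {self.mvc_target_bw}")
        if self.kind is Task.HOLD:
            if self.hold_level_bw is None or self.hold_level_bw <= 0:
                raise ValueError(f"hold_level_bw must be > 0, got {self.hold_level_bw}")
        return self

    # --- canonical task factories -----------------------------------------

    @classmethod
    def step(cls, **kw) -> "TaskSpec":
        return cls(kind=Task.STEP, **kw).validate()

    @classmethod
    def pulse(cls, **kw) -> "TaskSpec":
        kw.setdefault("on_duration_s", 0.05)
        kw.setdefault("off_duration_s", 6.95)
        return cls(kind=Task.PULSE, **kw).validate()

    @classmethod
    def mvc(cls, **kw) -> "TaskSpec":
        kw.setdefault("total_duration_s", 10.0)
        kw.setdefault("n_reps", 0)
        return cls(kind=Task.MVC, **kw).validate()

    @classmethod
    def hold(cls, level_bw: float, **kw) -> "TaskSpec":
        kw.setdefault("n_reps", 0)
        return cls(kind=Task.HOLD, hold_level_bw=level_bw, **kw).validate()

    @property
    def upper_bw(self) -> float:
        return self.baseline_bw + self.step_size_bw

    def onsets_s(self) -> tuple[float, ...]:
        """Target step-up times (trial clock) for STEP/PULSE tasks."""
        if self.kind not in (Task.STEP, Task.PULSE):
            return ()
        period = self.on_duration_s + self.off_duration_s
        return tuple(self.lead_in_s + k * period for k in range(self.n_reps))


def make_target_waveform(spec: TaskSpec) -> SampledTrace:
    """Render a task specification into the displayed target trace (BW)."""
    spec.validate()
    fs = spec.sample_rate_hz
    n = int(round(spec.total_duration_s * fs))
    if spec.kind is Task.MVC:
        level = spec.mvc_target_bw
        return SampledTrace(np.full(n, level), fs)
    if spec.kind is Task.HOLD:
        return SampledTrace(np.full(n, float(spec.hold_level_bw)), fs)
    values = np.full(n, spec.baseline_bw)
    for onset in spec.onsets_s():
        i0 = int(round(onset * fs))
        i1 = int(round((onset + spec.on_duration_s) * fs))
        values[i0:i1] = spec.upper_bw
    return SampledTrace(values, fs)


# ---------------------------------------------------------------------------
# The simulated participant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantParams:
    """Delay + linear second-order force plant with signal-dependent noise.

    ``natural_period_s`` is the undamped natural period ``T = 2*pi/omega_n``;
    rise time scales linearly with it.  ``damping_ratio`` sets overshoot
    (>= 1 cannot overshoot).  Output saturates at ``mvc_bw``.

    Noise is signal-dependent and band-limited below ``noise_band_hz``
    (physiological force variability lives well under the 10 Hz display
    filter).  Its SD tracks the *active* force above the passive standing
    support: ``noise_cv * (max(force - noise_rest_bw, 0) + noise_floor_bw)``.
    Tremor scales with active muscle drive, not with passive body weight --
    with noise proportional to total force, the between-step baseline (1 BW
    of mostly passive support) would carry as much tremor as a strong push,
    which neither physiology nor the response screen tolerates.  Setting
    ``noise_rest_bw = 0, noise_floor_bw = 0`` recovers plain
    proportional-to-force noise.
    """

    natural_period_s: float = 0.8852
    damping_ratio: float = 0.708
    motor_delay_s: float = 0.100
    noise_cv: float = 0.0148
    drift_per_s: float = 0.0
    mvc_bw: float = 2.95
    noise_band_hz: float = 8.0
    noise_rest_bw: float = 1.0
    noise_floor_bw: float = 0.1

    def validate(self) -> "PlantParams":
        if self.natural_period_s <= 0:
            raise ValueError(f"natural_period_s must be > 0, got {self.natural_period_s}")
        if self.damping_ratio <= 0:
            raise ValueError(f"damping_ratio must be > 0, got {self.damping_ratio}")
        for name in ("motor_delay_s", "noise_cv", "mvc_bw", "noise_band_hz",
                     "noise_rest_bw", "noise_floor_bw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self

    @property
    def omega_n(self) -> float:
        return 2.0 * np.pi / self.natural_period_s


def default_plant() -> PlantParams:
    return PlantParams().validate()


def simulate_force_response(
    target: SampledTrace,
    plant: PlantParams,
    seed: int,
    *,
    command: SampledTrace | None = None,
) -> SampledTrace:
    """Simulate the measured force (BW) while tracking ``target``.

    ``command`` is the internal motor command driving the plant; it defaults
    to the target itself.  (MVC and hold trials use a ramped command: people
    build force over seconds even when the displayed target is constant.)

    The plant is discretized with a zero-order hold at the trace sample
    rate, which is *exact* for piecewise-constant commands -- a noiseless
    run reproduces the analytic second-order step response at the sample
    instants.  Deterministic for a fixed seed.
    """
    if not isinstance(target, SampledTrace):
        raise TypeError("target must be a SampledTrace (uniformly sampled)")
    plant.validate()
    u_trace = command if command is not None else target
    if u_trace.n != target.n or u_trace.sample_rate_hz != target.sample_rate_hz:
        raise ValueError("command and target must share sample rate and length")
    fs = target.sample_rate_hz
    u = u_trace.values

    # Pure motor delay, rounded to whole samples.
    k = int(round(plant.motor_delay_s * fs))
    if k > 0:
        u = np.concatenate([np.full(k, u[0]), u[:-k]])

    wn, z = plant.omega_n, plant.damping_ratio
    numd, dend, _ = sps.cont2discrete(([wn**2], [1.0, 2.0 * z * wn, wn**2]), 1.0 / fs, method="zoh")
    b, a = numd.ravel(), dend.ravel()
    zi = sps.lfilter_zi(b, a) * u[0]
    clean, _ = sps.lfilter(b, a, u, zi=zi)
    np.clip(clean, 0.0, plant.mvc_bw, out=clean)

    out = clean
    if plant.noise_cv > 0:
        rng = np.random.default_rng(seed)
        e = rng.standard_normal(clean.size)
        if plant.noise_band_hz > 0 and plant.noise_band_hz < fs / 2:
            sos = sps.butter(2, plant.noise_band_hz, btype="lowpass", fs=fs, output="sos")
            e = sps.sosfilt(sos, e)
            e = e / e.std()
        sd = plant.noise_cv * (np.maximum(clean - plant.noise_rest_bw, 0.0) + plant.noise_floor_bw)
        out = clean + sd * e
    if plant.drift_per_s != 0:
        out = out + plant.drift_per_s * (np.arange(clean.size) / fs)
    return SampledTrace(out, fs, target.t0_s)


# ---------------------------------------------------------------------------
# Surface EMG
# ---------------------------------------------------------------------------

#: Per-muscle shaping bands (Hz).  Flat bands, so the expected median
#: frequency is the band midpoint; midpoints follow typical baseline values
#: for these muscles (gastrocnemii ~126-133 Hz, biceps femoris ~90 Hz).
DEFAULT_EMG_BANDS: dict[str, tuple[float, float]] = {
    "vastus_medialis": (75.0, 185.0),
    "vastus_lateralis": (70.0, 180.0),
    "rectus_femoris": (65.0, 175.0),
    "biceps_femoris": (45.0, 135.0),
    "gastroc_medialis": (73.0, 193.0),
    "gastroc_lateralis": (66.0, 186.0),
}


@dataclass(frozen=True)
class EMGParams:
    sample_rate_hz: float = 2000.0
    bands_hz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EMG_BANDS)
    )
    amplitude_gain: float = 5e-4  # Volts per BW of force

    def validate(self) -> "EMGParams":
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        nyq = self.sample_rate_hz / 2
        for name, (lo, hi) in self.bands_hz.items():
            if not 0 < lo < hi < nyq:
                raise ValueError(
                    f"band for {name!r} must satisfy 0 < low < high < Nyquist ({nyq} Hz), "
                    f"got ({lo}, {hi})"
                )
        return self


def default_emg_params() -> EMGParams:
    return EMGParams().validate()


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise with an ideally flat spectrum on ``band``."""
    e = rng.standard_normal(n)
    spectrum = np.fft.rfft(e)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spectrum, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_emg(
    force: SampledTrace,
    params: EMGParams,
    mdf_shift: float | tuple[float, float],
    seed: int,
) -> EMGChannelSet:
    """Six channels of band-shaped noise, amplitude-modulated by force.

    ``mdf_shift`` multiplies each channel's spectral position: a scalar
    applies uniformly; a ``(start, end)`` pair ramps linearly across the
    trial (fatigue developing within a hold).  The amplitude envelope is the
    force trace resampled onto the EMG clock times ``amplitude_gain``.
    """
    params.validate()
    shift = (float(mdf_shift), float(mdf_shift)) if np.isscalar(mdf_shift) else tuple(mdf_shift)
    if min(shift) <= 0:
        raise ValueError(f"mdf_shift must be > 0, got {shift}")
    smax = max(shift)
    nyq = params.sample_rate_hz / 2
    for name, (lo, hi) in params.bands_hz.items():
        if hi * smax >= nyq:
            raise ValueError(
                f"shifted band for {name!r} reaches {hi * smax:.0f} Hz >= Nyquist {nyq:.0f} Hz"
            )

    fs = params.sample_rate_hz
    n = int(round(force.duration_s * fs))
    t = np.arange(n) / fs
    envelope = params.amplitude_gain * np.interp(t, force.times_s - force.t0_s, force.values)
    rng = np.random.default_rng(seed)

    ramped = shift[0] != shift[1]
    s_t = np.linspace(shift[0], shift[1], n)
    channels = {}
    for name in MUSCLES:
        band = params.bands_hz[name]
        if not ramped:
            x = _shaped_noise(rng, n, fs, (band[0] * shift[0], band[1] * shift[0]))
        else:
            # Time-varying shift: read fixed-band noise at a varying rate.
            # Advancing through the source at s(t) samples/sample multiplies
            # every instantaneous frequency by s(t).
            pos = np.concatenate([[0.0], np.cumsum(s_t[:-1])])
            n_src = int(np.ceil(pos[-1])) + 2
            x_src = _shaped_noise(rng, n_src, fs, band)
            x = np.interp(pos, np.arange(n_src), x_src)
        channels[name] = SampledTrace(envelope * x, fs, force.t0_s)
    return EMGChannelSet(channels)


# ---------------------------------------------------------------------------
# Fatigue profile and whole-session simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionEffects:
    """Multipliers applied to the plant/EMG in one condition."""

    mvc_scale: float = 1.0
    rise_scale: float = 1.0
    cv_scale: float = 1.0
    mdf_shift: float = 1.0

    def validate(self) -> "ConditionEffects":
        for name in ("mvc_scale", "rise_scale", "cv_scale", "mdf_shift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        return self


@dataclass(frozen=True)
class FatigueProfile:
    """Per-condition fatigue multipliers, keyed by the five conditions."""

    effects: dict[Condition, ConditionEffects]

    def validate(self) -> "FatigueProfile":
        missing = set(Condition) - set(self.effects)
        if missing:
            raise ValueError(f"profile missing condition(s): {sorted(c.value for c in missing)}")
        for eff in self.effects.values():
            eff.validate()
        return self

    def __getitem__(self, condition: Condition) -> ConditionEffects:
        return self.effects[Condition(condition)]

    @classmethod
    def flat(cls) -> "FatigueProfile":
        """No programmed fatigue (all multipliers 1)."""
        return cls({c: ConditionEffects() for c in Condition}).validate()


def default_profile() -> FatigueProfile:
    """Endpoint effects at Fatigue3: -26.1% MVC, x1.233 rise time, x4.6
    hold CV, x0.897 EMG spectral position; intermediates roughly geometric."""
    return FatigueProfile(
        {
            Condition.TRAINING: ConditionEffects(),
            Condition.PRE_FATIGUE: ConditionEffects(),
            Condition.FATIGUE_1: ConditionEffects(0.870, 1.100, 2.20, 0.960),
            Condition.FATIGUE_2: ConditionEffects(0.800, 1.170, 3.40, 0.930),
            Condition.FATIGUE_3: ConditionEffects(0.739, 1.233, 4.60, 0.897),
        }
    ).validate()


#: Pulse-task behavior: a brief feedforward push.  The effective motor
#: command widens the 0.05-s pulse to PULSE_COMMAND_FRAC of the pulse
#: plant's natural period (long enough to near the target whatever the
#: participant's speed), driven through a plant PULSE_SPEED_FACTOR times
#: faster than the step plant and with a shorter anticipatory delay.
#: Fatigue scalings are *not* applied to pulse trials (feedforward control
#: is resilient to the fatigue the protocol induces).
PULSE_SPEED_FACTOR = 0.473
PULSE_COMMAND_FRAC = 0.462
PULSE_DELAY_S = 0.05

#: Between-participant spread (lognormal sigma on the natural period and the
#: noise CV; normal SD on maximal force in BW; lognormal sigma on damping and
#: on the shared fatigue-susceptibility exponent).
SUBJECT_SPREAD = {
    "period_sigma": 0.30,
    "mvc_sd_bw": 0.58,
    "damping_sigma": 0.07,
    "noise_sigma": 0.45,
    "susceptibility_sigma": 0.25,
    "trial_period_sigma": 0.05,
    "body_mass_mean_kg": 74.0,
    "body_mass_sd_kg": 16.0,
}

#: Trial sequence per condition: (task, ...) in execution order.
PROTOCOL: dict[Condition, tuple[Task, ...]] = {
    Condition.TRAINING: (Task.MVC, Task.MVC, Task.STEP, Task.STEP, Task.STEP),
    Condition.PRE_FATIGUE: (
        Task.MVC, Task.MVC, Task.STEP, Task.STEP, Task.STEP,
        Task.PULSE, Task.PULSE, Task.HOLD,
    ),
    Condition.FATIGUE_1: (
        Task.HOLD, Task.MVC, Task.HOLD, Task.MVC, Task.HOLD, Task.MVC,
        Task.STEP, Task.STEP, Task.STEP,
    ),
    Condition.FATIGUE_2: (
        Task.HOLD, Task.MVC, Task.HOLD, Task.MVC, Task.HOLD, Task.MVC,
        Task.STEP, Task.STEP, Task.STEP,
    ),
    Condition.FATIGUE_3: (
        Task.HOLD, Task.MVC, Task.HOLD, Task.MVC, Task.HOLD, Task.MVC,
        Task.STEP, Task.STEP, Task.STEP, Task.PULSE, Task.PULSE,
    ),
}

_G = 9.80665

#: Force-plate sampling rate used throughout.
FORCE_RATE_HZ = 1000.0


def trial_seed(master_seed: int, participant: str, condition: Condition, task: Task, repetition: int) -> int:
    """Stable per-trial seed derived from the master seed and trial identity."""
    key = f"{master_seed}|{participant}|{Condition(condition).value}|{Task(task).value}|{repetition}"
    digest = hashlib.blake2s(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _ramp_command(target: SampledTrace, start_bw: float, ramp_s: float) -> SampledTrace:
    """Command rising linearly from ``start_bw`` to the target level."""
    t = target.times_s - target.t0_s
    level = target.values
    frac = np.clip(t / ramp_s, 0.0, 1.0) if ramp_s > 0 else 1.0
    return target.with_values(start_bw + (level - start_bw) * frac)


def simulate_trial(
    spec: TaskSpec,
    plant: PlantParams,
    seed: int,
    *,
    participant_id: str = "P01",
    condition: Condition = Condition.PRE_FATIGUE,
    repetition: int = 1,
    body_weight_n: float = 74.0 * _G,
    emg_params: EMGParams | None = None,
    mdf_shift: float | tuple[float, float] = 1.0,
    include_emg: bool = False,
) -> TrialRecord:
    """Simulate one trial of any task kind against a given plant."""
    target = make_target_waveform(spec)
    command = None
    if spec.kind is Task.MVC:
        command = _ramp_command(target, spec.baseline_bw, 3.0)
    elif spec.kind is Task.HOLD:
        command = _ramp_command(target, spec.baseline_bw, 2.0)
    elif spec.kind is Task.PULSE:
        width = PULSE_COMMAND_FRAC * plant.natural_period_s
        widened = replace(spec, on_duration_s=width,
                          off_duration_s=spec.on_duration_s + spec.off_duration_s - width)
        command = make_target_waveform(widened)
    force = simulate_force_response(target, plant, seed, command=command)
    emg = None
    if include_emg:
        emg = simulate_emg(force, emg_params or default_emg_params(), mdf_shift, seed + 1)
    return TrialRecord(
        participant_id=participant_id,
        condition=condition,
        task=spec.kind,
        repetition=repetition,
        body_weight_n=body_weight_n,
        force=force,
        target=target,
        emg=emg,
        onsets_s=spec.onsets_s() or None,
        on_duration_s=spec.on_duration_s if spec.kind in (Task.STEP, Task.PULSE) else None,
        meta={"mdf_shift": mdf_shift if np.isscalar(mdf_shift) else tuple(mdf_shift)},
    )


def _draw_participant(rng: np.random.Generator, base: PlantParams, index: int) -> dict:
    mass = float(np.clip(rng.normal(SUBJECT_SPREAD["body_mass_mean_kg"],
                                    SUBJECT_SPREAD["body_mass_sd_kg"]), 45.0, 120.0))
    return {
        "id": f"P{index + 1:02d}",
        "body_weight_n": mass * _G,
        "period_s": base.natural_period_s * float(np.exp(rng.normal(0, SUBJECT_SPREAD["period_sigma"]))),
        "mvc_bw": float(np.clip(rng.normal(base.mvc_bw, SUBJECT_SPREAD["mvc_sd_bw"]), 1.7, 4.8)),
        "damping": base.damping_ratio * float(np.exp(rng.normal(0, SUBJECT_SPREAD["damping_sigma"]))),
        "noise_cv": base.noise_cv * float(np.exp(rng.normal(0, SUBJECT_SPREAD["noise_sigma"]))),
        # Shared fatigue susceptibility; E[g] = 1 so programmed group-mean
        # effect ratios are recovered without bias.
        "susceptibility": float(np.exp(
            rng.normal(0, SUBJECT_SPREAD["susceptibility_sigma"])
            - SUBJECT_SPREAD["susceptibility_sigma"] ** 2 / 2
        )),
    }


def simulate_session(
    base_plant: PlantParams | None = None,
    profile: FatigueProfile | None = None,
    seed: int = 0,
    *,
    n_participants: int = 18,
    emg_policy: Literal["none", "endpoints", "holds"] = "holds",
    emg_params: EMGParams | None = None,
    heterogeneous: bool = True,
) -> list[TrialRecord]:
    """Simulate the full five-condition protocol for a cohort.

    Per condition: Training = 2 MVC + 3 Step; Pre-Fatigue = 2 MVC + 3 Step +
    2 Pulse + 1 practice Hold; each Fatigue condition = (Hold + MVC) x 3 then
    3 Step, with 2 Pulse appended after Fatigue-3.  Plant parameters are
    scaled by the condition's fatigue effects (raised to the participant's
    susceptibility exponent); pulse trials keep pre-fatigue dynamics.

    ``emg_policy`` selects which hold trials carry EMG: every hold
    (``"holds"``), only the first hold of Fatigue-1 and last of Fatigue-3
    (``"endpoints"`` -- all the median-frequency comparison needs), or none.
    """
    base = (base_plant or default_plant()).validate()
    prof = (profile or default_profile()).validate()
    emg_p = (emg_params or default_emg_params()).validate()
    rng = np.random.default_rng(seed)

    trials: list[TrialRecord] = []
    for idx in range(n_participants):
        if heterogeneous:
            p = _draw_participant(rng, base, idx)
        else:
            p = {
                "id": f"P{idx + 1:02d}",
                "body_weight_n": SUBJECT_SPREAD["body_mass_mean_kg"] * _G,
                "period_s": base.natural_period_s,
                "mvc_bw": base.mvc_bw,
                "damping": base.damping_ratio,
                "noise_cv": base.noise_cv,
                "susceptibility": 1.0,
            }
        g = p["susceptibility"]
        hold_level = 1.0 + 0.25 * p["mvc_bw"]  # 1 BW + 25% of pre-fatigue MVC

        prev_mdf = 1.0
        for condition in Condition.ordered():
            eff = prof[condition]
            mvc_c = p["mvc_bw"] * eff.mvc_scale**g
            period_c = p["period_s"] * eff.rise_scale**g
            noise_c = p["noise_cv"] * eff.cv_scale**g
            mdf_c = eff.mdf_shift**g

            seq = PROTOCOL[condition]
            n_holds = sum(1 for t in seq if t is Task.HOLD)
            reps = {t: 0 for t in Task}
            hold_idx = 0
            for task in seq:
                reps[task] += 1
                rep = reps[task]
                tseed = trial_seed(seed, p["id"], condition, task, rep)
                jitter = 1.0
                if heterogeneous:
                    jrng = np.random.default_rng(tseed + 7)
                    jitter = float(np.exp(jrng.normal(0, SUBJECT_SPREAD["trial_period_sigma"])))

                if task is Task.PULSE:
                    plant = PlantParams(
                        natural_period_s=p["period_s"] * PULSE_SPEED_FACTOR * jitter,
                        damping_ratio=p["damping"],
                        motor_delay_s=PULSE_DELAY_S,
                        noise_cv=p["noise_cv"],
                        drift_per_s=base.drift_per_s,
                        mvc_bw=p["mvc_bw"],
                        noise_band_hz=base.noise_band_hz,
                        noise_rest_bw=base.noise_rest_bw,
                        noise_floor_bw=base.noise_floor_bw,
                    )
                else:
                    # variability growth is a sustained-contraction (hold)
                    # phenomenon; brief step/pulse efforts keep baseline
                    # tremor, matching preserved accuracy under fatigue
                    trial_noise = noise_c if task in (Task.HOLD, Task.MVC) else p["noise_cv"]
                    plant = PlantParams(
                        natural_period_s=period_c * jitter,
                        damping_ratio=p["damping"],
                        motor_delay_s=base.motor_delay_s,
                        noise_cv=trial_noise,
                        drift_per_s=base.drift_per_s,
                        mvc_bw=mvc_c,
                        noise_band_hz=base.noise_band_hz,
                        noise_rest_bw=base.noise_rest_bw,
                        noise_floor_bw=base.noise_floor_bw,
                    )

                if task is Task.MVC:
                    spec = TaskSpec.mvc(sample_rate_hz=FORCE_RATE_HZ)
                elif task is Task.HOLD:
                    spec = TaskSpec.hold(hold_level, sample_rate_hz=FORCE_RATE_HZ)
                elif task is Task.STEP:
                    spec = TaskSpec.step(sample_rate_hz=FORCE_RATE_HZ)
                else:
                    spec = TaskSpec.pulse(sample_rate_hz=FORCE_RATE_HZ)

                mdf = 1.0
                include_emg = False
                if task is Task.HOLD:
                    if condition is Condition.PRE_FATIGUE:
                        mdf = (1.0, 1.0)
                    else:
                        hold_idx += 1
                        lo = prev_mdf + (hold_idx - 1) / n_holds * (mdf_c - prev_mdf)
                        hi = prev_mdf + hold_idx / n_holds * (mdf_c - prev_mdf)
                        mdf = (lo, hi)
                    if emg_policy == "holds":
                        include_emg = True
                    elif emg_policy == "endpoints":
                        include_emg = (
                            (condition is Condition.FATIGUE_1 and hold_idx == 1)
                            or (condition is Condition.FATIGUE_3 and hold_idx == n_holds)
                        )

                trial = simulate_trial(
                    spec, plant, tseed,
                    participant_id=p["id"], condition=condition, repetition=rep,
                    body_weight_n=p["body_weight_n"], emg_params=emg_p,
                    mdf_shift=mdf, include_emg=include_emg,
                )
                trial.meta["order"] = len(trials)
                trials.append(trial)
            if any(t is Task.HOLD for t in seq) and condition is not Condition.PRE_FATIGUE:
                prev_mdf = mdf_c
    return trials


def iter_participants(trials: Iterable[TrialRecord]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for tr in trials:
        seen.setdefault(tr.participant_id, None)
    return tuple(seen)
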