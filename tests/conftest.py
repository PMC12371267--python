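"""Shared fixtures: hand-built response segments and noiseless plants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from legforce.config import default_config
from legforce.segment import ResponseSegment
from legforce.synth import PlantParams, TaskSpec, simulate_trial
from legforce.trace import Condition, SampledTrace, Task

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def cfg():
    return default_config()


@pytest.fixture
def noiseless_plant():
    return PlantParams(noise_cv=0.0, drift_per_s=0.0)


def make_segment(
    values: np.ndarray,
    *,
    fs: float = 1000.0,
    task: Task = Task.STEP,
    onset_seg_s: float = 1.0,
    on_s: float = 4.0,
    baseline: float = 1.0,
    step: float = 0.4,
    t0: float = 0.0,
) -> ResponseSegment:
    """Wrap a bare force array as a response segment (target rebuilt to match)."""
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.size) / fs
    target = np.where(
        (t >= t0 + onset_seg_s) & (t < t0 + onset_seg_s + on_s), baseline + step, baseline
    )
    return ResponseSegment(
        participant_id="TEST",
        condition=Condition.PRE_FATIGUE,
        task=task,
        repetition=1,
        step_index=0,
        window_trial_s=(t0, t0 + values.size / fs),
        onset_trial_s=t0 + onset_seg_s,
        onset_seg_s=t0 + onset_seg_s,
        stepdown_seg_s=t0 + onset_seg_s + on_s,
        baseline_bw=baseline,
        step_size_bw=step,
        force=SampledTrace(values, fs, t0),
        target=SampledTrace(target, fs, t0),
    )


def single_step_trial(plant: PlantParams, seed: int = 0, **spec_kw):
    """One-step trial (onset 2 s, 4 s on) for focused metric tests."""
    spec_kw.setdefault("n_reps", 1)
    spec_kw.setdefault("lead_in_s", 2.0)
    spec_kw.setdefault("total_duration_s", 9.0)
    return simulate_trial(TaskSpec.step(**spec_kw), plant, seed)


@pytest.fixture
def clean_step_segment(noiseless_plant):
    from legforce.segment import segment_step_task

    trial = single_step_trial(noiseless_plant)
    return segment_step_task(trial)[0]
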