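"""Generator behavior: target geometry, plant physics, EMG spectra, protocol."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from legforce.emg_spectra import median_frequency
from legforce.metrics import mvc_mean, overshoot, rise_time
from legforce.segment import segment_step_task
from legforce.synth import (
    EMGParams,
    FatigueProfile,
    PlantParams,
    TaskSpec,
    default_profile,
    make_target_waveform,
    simulate_emg,
    simulate_force_response,
    simulate_session,
    simulate_trial,
    trial_seed,
)
from legforce.trace import Condition, SampledTrace, Task

from conftest import single_step_trial


class TestTargetWaveform:
    def test_step_geometry(self):
        """Default step target: 73 000 samples, ten 4-s plateaus at 1.4 BW."""
        trace = make_target_waveform(TaskSpec.step())
        assert trace.n == 73_000
        high = np.isclose(trace.values, 1.4)
        assert high.sum() == 10 * 4_000
        # each on-phase is one contiguous 4000-sample run
        edges = np.flatnonzero(np.diff(high.astype(int)))
        assert edges.size == 20

    def test_pulse_high_interval_is_50_samples(self):
        trace = make_target_waveform(TaskSpec.pulse())
        high = np.flatnonzero(trace.values > 1.2)
        runs = np.split(high, np.flatnonzero(np.diff(high) > 1) + 1)
        assert len(runs) == 10
        assert all(r.size == 50 for r in runs)

    def test_zero_reps_is_constant_baseline(self):
        trace = make_target_waveform(TaskSpec.step(n_reps=0))
        assert np.all(trace.values == 1.0)

    def test_invalid_spec_names_violated_invariant(self):
        with pytest.raises(ValueError, match="total_duration_s"):
            TaskSpec.step(n_reps=20)
        with pytest.raises(ValueError, match="step_size_bw"):
            TaskSpec.step(step_size_bw=-0.1)
        with pytest.raises(ValueError, match="sample_rate_hz"):
            TaskSpec.step(sample_rate_hz=0)

    @given(n_reps=st.integers(0, 10), on=st.floats(0.05, 4.0), off=st.floats(0.5, 3.0))
    def test_regeneration_is_idempotent(self, n_reps, on, off):
        spec = TaskSpec(
            kind=Task.STEP, n_reps=n_reps, on_duration_s=on, off_duration_s=off,
            total_duration_s=3.0 + n_reps * (on + off) + 1.0,
        ).validate()
        a = make_target_waveform(spec)
        b = make_target_waveform(spec)
        assert np.array_equal(a.values, b.values)
        assert len(spec.onsets_s()) == n_reps


class TestForcePlant:
    def test_identical_seeds_give_bit_identical_traces(self):
        target = make_target_waveform(TaskSpec.step())
        plant = PlantParams()
        a = simulate_force_response(target, plant, seed=42)
        b = simulate_force_response(target, plant, seed=42)
        assert np.array_equal(a.values, b.values)
        c = simulate_force_response(target, plant, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_noiseless_matches_analytic_second_order_response(self):
        """ZOH discretization reproduces the closed-form underdamped step
        response at the sample instants (<= 1e-6 BW RMS)."""
        fs, t_on, delay = 1000.0, 2.0, 0.1
        z, T = 0.6, 0.8
        wn = 2 * np.pi / T
        n = int(8 * fs)
        target = SampledTrace(np.where(np.arange(n) / fs >= t_on, 1.4, 1.0), fs)
        plant = PlantParams(natural_period_s=T, damping_ratio=z, motor_delay_s=delay,
                            noise_cv=0, drift_per_s=0, mvc_bw=10)
        sim = simulate_force_response(target, plant, seed=0)

        t = np.arange(n) / fs - (t_on + delay)
        wd = wn * np.sqrt(1 - z**2)
        h = 1 - np.exp(-z * wn * t) * (np.cos(wd * t) + z / np.sqrt(1 - z**2) * np.sin(wd * t))
        analytic = 1.0 + 0.4 * np.where(t >= 0, h, 0.0)
        rms = np.sqrt(np.mean((sim.values - analytic) ** 2))
        assert rms <= 1e-6

    def test_overdamped_response_cannot_overshoot(self):
        plant = PlantParams(damping_ratio=1.2, noise_cv=0, drift_per_s=0)
        seg = segment_step_task(single_step_trial(plant))[0]
        assert overshoot(seg) <= 0.0
        # monotone rise between the threshold crossings
        rt = rise_time(seg)
        assert rt is not None and rt > 0

    def test_underdamped_overshoot_matches_closed_form(self):
        """Peak overshoot for damping 0.5 equals exp(-pi*z/sqrt(1-z^2))."""
        z = 0.5
        plant = PlantParams(damping_ratio=z, noise_cv=0, drift_per_s=0)
        seg = segment_step_task(single_step_trial(plant))[0]
        expected = 100.0 * np.exp(-np.pi * z / np.sqrt(1 - z**2))
        assert overshoot(seg) == pytest.approx(expected, abs=0.1)

    def test_mvc_saturates_at_plant_maximum(self):
        plant = PlantParams(mvc_bw=2.2, noise_cv=0, drift_per_s=0)
        trial = simulate_trial(TaskSpec.mvc(), plant, seed=0)
        assert mvc_mean(trial).mean_force_bw == pytest.approx(2.2, abs=1e-9)

    def test_noise_scales_with_active_force(self):
        """Baseline (passive standing) carries far less tremor than a push."""
        plant = PlantParams(noise_cv=0.02, drift_per_s=0)
        trial = single_step_trial(plant, seed=3)
        resid = trial.force.values - single_step_trial(
            PlantParams(noise_cv=0, drift_per_s=0), seed=3
        ).force.values
        t = trial.force.times_s
        sd_base = resid[t < 1.5].std()
        sd_push = resid[(t > 4.0) & (t < 5.5)].std()
        assert sd_push > 3 * sd_base


class TestEMG:
    def test_flat_band_median_frequency_is_band_center(self):
        force = SampledTrace(np.full(4000, 1.5), 1000.0)
        params = EMGParams(bands_hz={m: (60.0, 140.0) for m in EMGParams().bands_hz})
        emg = simulate_emg(force, params, mdf_shift=1.0, seed=0)
        mdf = median_frequency(emg["gastroc_lateralis"])
        assert mdf == pytest.approx(100.0, abs=4.0)

    def test_mdf_shift_scales_spectrum_linearly(self):
        force = SampledTrace(np.full(4000, 1.5), 1000.0)
        params = EMGParams(bands_hz={m: (60.0, 140.0) for m in EMGParams().bands_hz})
        emg = simulate_emg(force, params, mdf_shift=0.9, seed=0)
        assert median_frequency(emg["gastroc_lateralis"]) == pytest.approx(90.0, abs=4.0)

    def test_zero_force_gives_all_zero_channels(self):
        force = SampledTrace(np.zeros(2000), 1000.0)
        emg = simulate_emg(force, EMGParams(), mdf_shift=1.0, seed=0)
        for name in emg.names:
            assert np.all(emg[name].values == 0.0)

    def test_shift_beyond_nyquist_rejected(self):
        force = SampledTrace(np.full(2000, 1.5), 1000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_emg(force, EMGParams(), mdf_shift=6.0, seed=0)

    def test_ramped_shift_compresses_spectrum_over_time(self):
        """A (1.0 -> 0.8) within-trial ramp shows up as the matching
        first-to-last window MDF ratio (mean over seeds)."""
        force = SampledTrace(np.full(20_000, 1.5), 1000.0)  # 20 s
        params = EMGParams(bands_hz={m: (60.0, 140.0) for m in EMGParams().bands_hz})
        ratios = []
        for seed in range(5):
            ch = simulate_emg(force, params, mdf_shift=(1.0, 0.8), seed=seed)["gastroc_lateralis"]
            ratios.append(median_frequency(ch.crop(16, 20)) / median_frequency(ch.crop(0, 4)))
        # window centers at 2 s and 18 s -> expected 0.82 / 0.98 = 0.837
        assert np.mean(ratios) == pytest.approx(0.837, abs=0.04)


class TestSession:
    def test_pre_fatigue_block_inventory(self):
        """Pre-Fatigue: 2 MVC + 3 Step + 2 Pulse + 1 practice hold."""
        trials = simulate_session(seed=1, n_participants=1, emg_policy="none")
        pre = [t for t in trials if t.condition is Condition.PRE_FATIGUE]
        counts = {k: sum(1 for t in pre if t.task is k) for k in Task}
        assert counts == {Task.MVC: 2, Task.STEP: 3, Task.PULSE: 2, Task.HOLD: 1}

    def test_fatigue_block_inventory(self):
        trials = simulate_session(seed=1, n_participants=1, emg_policy="none")
        for cond in (Condition.FATIGUE_1, Condition.FATIGUE_2):
            blk = [t for t in trials if t.condition is cond]
            counts = {k: sum(1 for t in blk if t.task is k) for k in Task}
            assert counts == {Task.MVC: 3, Task.STEP: 3, Task.PULSE: 0, Task.HOLD: 3}
        f3 = [t for t in trials if t.condition is Condition.FATIGUE_3]
        assert sum(1 for t in f3 if t.task is Task.PULSE) == 2

    def test_flat_profile_produces_no_rise_time_trend(self):
        """All multipliers 1 -> condition rise-time means differ only by noise."""
        from legforce.metrics import compute_step_metrics
        from legforce.preprocess import filter_force

        means = {c: [] for c in Condition}
        for seed in range(4):
            trials = simulate_session(
                profile=FatigueProfile.flat(), seed=seed, n_participants=3, emg_policy="none"
            )
            for tr in trials:
                if tr.task is not Task.STEP:
                    continue
                segs = segment_step_task(tr, force=filter_force(tr.force))
                vals = [compute_step_metrics(s).rise_time_ms for s in segs[:5]]
                means[tr.condition].extend(v for v in vals if np.isfinite(v))
        cond_means = np.array([np.mean(means[c]) for c in Condition.ordered()])
        slope = np.polyfit(np.arange(5), cond_means, 1)[0]
        assert abs(slope) < 8.0  # ms per condition: no programmed trend

    def test_trial_seed_is_stable_and_in_range(self):
        s1 = trial_seed(7, "P01", Condition.FATIGUE_1, Task.STEP, 2)
        s2 = trial_seed(7, "P01", Condition.FATIGUE_1, Task.STEP, 2)
        assert s1 == s2 and 0 <= s1 < 2**31
        assert s1 != trial_seed(7, "P01", Condition.FATIGUE_1, Task.STEP, 3)
        assert s1 != trial_seed(8, "P01", Condition.FATIGUE_1, Task.STEP, 2)

    def test_default_profile_validates_and_covers_all_conditions(self):
        prof = default_profile()
        assert set(prof.effects) == set(Condition)
        with pytest.raises(ValueError, match="missing condition"):
            FatigueProfile({Condition.TRAINING: prof[Condition.TRAINING]}).validate()
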