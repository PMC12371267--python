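"""Response characteristics against constructed signals and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from legforce.config import MetricsConfig
from legforce.metrics import (
    bandwidth,
    compute_step_metrics,
    fall_time,
    hold_variability,
    mvc_mean,
    overshoot,
    rise_time,
    steady_state_error,
    steady_state_variability,
)
from legforce.segment import segment_step_task
from legforce.synth import PlantParams, TaskSpec, simulate_trial
from legforce.trace import SampledTrace

from conftest import make_segment, single_step_trial

FS = 1000.0


def ramp_segment(ramp_s: float, *, onset=1.0, on_s=4.0, total=6.0, start_at_onset=0.0):
    """Force ramping linearly baseline -> upper over ``ramp_s`` from onset."""
    t = np.arange(int(total * FS)) / FS
    t_on = onset + start_at_onset
    frac = np.clip((t - t_on) / ramp_s, 0, 1) if ramp_s > 0 else (t >= t_on).astype(float)
    return make_segment(1.0 + 0.4 * frac, onset_seg_s=onset, on_s=on_s)


class TestRiseTime:
    def test_half_second_ramp_rises_in_400_ms(self):
        assert rise_time(ramp_segment(0.5)) == pytest.approx(400.0, abs=1e-6)

    def test_instantaneous_step_rises_within_one_sample(self):
        rt = rise_time(ramp_segment(0.0))
        assert rt is not None and rt <= 1000.0 / FS

    def test_threshold_never_crossed_is_uncomputable(self):
        seg = make_segment(np.full(6000, 1.0))
        assert rise_time(seg) is None
        assert compute_step_metrics(seg).flags["rise_time_ms"] is False

    def test_rise_outside_search_window_is_uncomputable(self):
        # rise starts 1.2 s after onset: past the [onset-0.5, onset+1) window
        assert rise_time(ramp_segment(0.3, start_at_onset=1.2)) is None

    def test_noiseless_second_order_matches_dense_brute_force(self):
        """Interpolated crossings vs a 100 kHz threshold search, within 1 ms."""
        plant = PlantParams(natural_period_s=0.876, damping_ratio=1.0, noise_cv=0, drift_per_s=0)
        seg = segment_step_task(single_step_trial(plant))[0]
        rt = rise_time(seg)
        t = seg.force.times_s
        t_dense = np.arange(0.5, 2.0, 1e-5)
        y = np.interp(t_dense, t, seg.force.values)
        t10 = t_dense[np.argmax(y >= 1.04)]
        t90 = t_dense[np.argmax(y >= 1.36)]
        assert rt == pytest.approx((t90 - t10) * 1000.0, abs=1.0)


class TestBandwidth:
    @pytest.mark.parametrize(
        "rise_ms, expected_hz", [(350.0, 1.0), (500.0, 0.7), (303.0, 0.35 / 0.303)]
    )
    def test_definition(self, rise_ms, expected_hz):
        assert bandwidth(rise_ms) == pytest.approx(expected_hz, rel=1e-12)

    def test_zero_or_missing_rise_uncomputable(self):
        assert bandwidth(0.0) is None
        assert bandwidth(None) is None

    def test_mean_bandwidth_exceeds_bandwidth_of_mean_rise(self):
        """Averaging per-response bandwidths (a convex transform of rise
        time) exceeds 0.35 over the mean rise time -- the reason a 303 ms
        mean rise coexists with a 1.33 Hz mean bandwidth."""
        rng = np.random.default_rng(0)
        rises = rng.normal(303.0, 100.0, 500).clip(80, None)
        bws = np.array([bandwidth(r) for r in rises])
        assert bws.mean() > bandwidth(float(rises.mean()))

    def test_product_invariant_on_simulated_responses(self):
        for seed in range(5):
            seg = segment_step_task(single_step_trial(PlantParams(), seed=seed))[0]
            m = compute_step_metrics(seg)
            assert m.bandwidth_hz * m.rise_time_ms / 1000.0 == pytest.approx(0.35, abs=1e-12)


class TestFallTime:
    def test_linear_descent_over_one_second_falls_in_800_ms(self):
        t = np.arange(6000) / FS
        frac_up = np.clip((t - 1.0) / 0.2, 0, 1)
        frac_dn = np.clip((t - 4.5) / 1.0, 0, 1)  # descent within [4, 6) window
        seg = make_segment(1.0 + 0.4 * (frac_up - frac_dn))
        assert fall_time(seg) == pytest.approx(800.0, abs=1e-6)

    def test_instantaneous_drop_falls_within_one_sample(self):
        t = np.arange(6000) / FS
        y = np.where((t >= 1.0) & (t < 5.0), 1.4, 1.0)
        ft = fall_time(make_segment(y))
        assert ft is not None and ft <= 1000.0 / FS

    def test_noisy_descent_matches_dense_brute_force_within_5_ms(self):
        rng = np.random.default_rng(7)
        t = np.arange(6000) / FS
        frac_up = np.clip((t - 1.0) / 0.2, 0, 1)
        frac_dn = np.clip((t - 4.6) / 0.5, 0, 1)
        noise = np.convolve(rng.standard_normal(6000), np.ones(40) / 40, "same") * 0.01
        seg = make_segment(1.0 + 0.4 * (frac_up - frac_dn) + noise)
        ft = fall_time(seg)
        t_dense = np.arange(4.0, 6.0, 1e-5)
        y = np.interp(t_dense, t, seg.force.values)
        i90 = np.argmax(y <= 1.36)
        i10 = i90 + np.argmax(y[i90:] <= 1.04)
        assert ft == pytest.approx((t_dense[i10] - t_dense[i90]) * 1000.0, abs=5.0)


class TestAccuracyMetrics:
    def test_overshoot_arithmetic(self):
        t = np.arange(6000) / FS
        y = np.where((t >= 1.0) & (t < 5.0), 1.4, 1.0)
        y[1500] = 1.44  # peak 0.04 above target = 10% of the step
        assert overshoot(make_segment(y)) == pytest.approx(10.0, abs=1e-9)

    def test_overshoot_zero_when_peak_equals_target(self):
        t = np.arange(6000) / FS
        y = np.where((t >= 1.0) & (t < 5.0), 1.4, 1.0)
        assert overshoot(make_segment(y)) == pytest.approx(0.0, abs=1e-12)

    def test_overshoot_signed_negative_below_target(self):
        t = np.arange(6000) / FS
        y = np.where((t >= 1.0) & (t < 5.0), 1.38, 1.0)
        assert overshoot(make_segment(y)) == pytest.approx(-5.0, abs=1e-9)

    @pytest.mark.parametrize("level, expected", [(1.386, 1.0), (1.4, 0.0), (1.54, 10.0)])
    def test_steady_state_error_examples(self, level, expected):
        t = np.arange(6000) / FS
        y = np.where((t >= 1.0) & (t < 5.0), level, 1.0)
        assert steady_state_error(make_segment(y)) == pytest.approx(expected, abs=1e-9)

    def test_steady_state_variability_of_constant_is_zero(self):
        t = np.arange(6000) / FS
        y = np.where((t >= 1.0) & (t < 5.0), 1.4, 1.0)
        assert steady_state_variability(make_segment(y)) == pytest.approx(0.0, abs=1e-12)

    def test_known_sd_gives_one_percent_cv(self):
        t = np.arange(6000) / FS
        y = np.where((t >= 1.0) & (t < 5.0), 1.4, 1.0)
        win = (t >= 3.0) & (t < 5.0)
        y[win] += 0.014 * np.sign(np.sin(2 * np.pi * 50 * t[win]))  # SD exactly 0.014
        assert steady_state_variability(make_segment(y)) == pytest.approx(1.0, abs=0.01)

    def test_injected_gaussian_cv_recovered_over_seeds(self):
        """CV estimator is unbiased: 2% injected noise reads back as 2%."""
        t = np.arange(6000) / FS
        base = np.where((t >= 1.0) & (t < 5.0), 1.4, 1.0)
        ests = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = base + np.where(base > 1.2, 0.02 * 1.4 * rng.standard_normal(6000), 0)
            ests.append(steady_state_variability(make_segment(y)))
        assert np.mean(ests) == pytest.approx(2.0, abs=0.05)


class TestWholeTrialMeasures:
    def test_mvc_mean_of_constant(self):
        assert mvc_mean(SampledTrace(np.full(10_000, 2.95), FS)).mean_force_bw == pytest.approx(2.95)

    def test_mvc_mean_of_ramp(self):
        """0 -> 3 BW over 10 s averages 1.8 BW across the 4-8 s window."""
        trace = SampledTrace(np.linspace(0, 3, 10_000, endpoint=False), FS)
        assert mvc_mean(trace).mean_force_bw == pytest.approx(1.8, abs=1e-3)

    def test_short_mvc_uncomputable(self):
        assert mvc_mean(SampledTrace(np.full(5000, 2.0), FS)) is None

    def test_saturated_synthetic_mvc_recovers_plant_maximum(self):
        plant = PlantParams(mvc_bw=2.2)
        vals = [
            mvc_mean(simulate_trial(TaskSpec.mvc(), plant, seed=s).force).mean_force_bw
            for s in range(10)
        ]
        assert np.mean(vals) == pytest.approx(2.2, abs=0.02)

    def test_hold_73s_gives_68_segments(self):
        hm = hold_variability(SampledTrace(np.full(73_000, 1.74), FS))
        assert hm.cv_per_second_pct.size == 68
        assert np.all(hm.cv_per_second_pct < 1e-10)  # constant signal: CV ~ 0
        assert hm.final10_mean_cv_pct == pytest.approx(0.0, abs=1e-10)

    def test_short_hold_uncomputable(self):
        assert hold_variability(SampledTrace(np.full(10_000, 1.74), FS)) is None

    def test_injected_hold_cv_recovered(self):
        """0.61% multiplicative noise reads back as ~0.61% final-10 CV."""
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 1.74 * (1.0 + 0.0061 * rng.standard_normal(73_000))
            ests.append(hold_variability(SampledTrace(y, FS)).final10_mean_cv_pct)
        assert np.mean(ests) == pytest.approx(0.61, abs=0.02)


class TestInvariances:
    @given(shift=st.floats(-50.0, 50.0))
    def test_metrics_invariant_to_time_origin(self, shift):
        plant = PlantParams(noise_cv=0.01, drift_per_s=0)
        seg = segment_step_task(single_step_trial(plant, seed=11))[0]
        moved = make_segment(seg.force.values, t0=shift)
        for fn in (rise_time, fall_time, overshoot, steady_state_error, steady_state_variability):
            a, b = fn(seg), fn(moved)
            assert a == pytest.approx(b, abs=1e-9)

    def test_metrics_robust_to_dense_resampling(self):
        """Same segment at 10 kHz: timings within 1 ms, accuracy within 0.1 pp."""
        plant = PlantParams(noise_cv=0, drift_per_s=0)
        seg = segment_step_task(single_step_trial(plant))[0]
        t = seg.force.times_s
        t_hi = np.arange(0, 6.0, 1e-4)
        dense = make_segment(np.interp(t_hi, t, seg.force.values), fs=10_000.0)
        assert rise_time(dense) == pytest.approx(rise_time(seg), abs=1.0)
        assert fall_time(dense) == pytest.approx(fall_time(seg), abs=1.0)
        assert overshoot(dense) == pytest.approx(overshoot(seg), abs=0.1)
        assert steady_state_error(dense) == pytest.approx(steady_state_error(seg), abs=0.1)

    def test_rise_time_monotone_in_natural_period(self):
        periods = [0.5, 0.7, 0.9, 1.1, 1.3]
        rises = []
        for T in periods:
            plant = PlantParams(natural_period_s=T, noise_cv=0, drift_per_s=0)
            rises.append(rise_time(segment_step_task(single_step_trial(plant))[0]))
        assert np.all(np.diff(rises) > 0)

    def test_window_overrides_flow_through_config(self):
        cfg = MetricsConfig(rise_frac_lo=0.2, rise_frac_hi=0.8)
        seg = ramp_segment(0.5)
        assert rise_time(seg, cfg) == pytest.approx(300.0, abs=1e-6)
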