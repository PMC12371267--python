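"""End-to-end orchestration: generate/load -> preprocess -> segment ->
measure -> summarize -> test.

``analyze_session`` is the in-memory pipeline over a list of trials;
``run_pipeline`` wraps it with disk I/O, per-trial fault isolation, a run
manifest, and deterministic CSV outputs.  ``generate_fixtures`` writes a
miniature synthetic study plus adversarial single-response trials, one
engineered to fire each exclusion criterion.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as config_mod
from .config import AnalysisConfig, default_config
from .emg_spectra import mdf_fatigue_change, mdf_time_series
from .io import METRIC_COLUMNS, read_trial, write_metrics_table, write_trial
from .metrics import compute_step_metrics, hold_variability, mvc_mean
from .preprocess import correct_sensor_delay, filter_emg, filter_force
from .segment import (
    apply_pulse_exclusions,
    apply_step_exclusions,
    segment_pulse_task,
    segment_step_task,
)
from .stats import bonferroni_pairwise, cohens_d, rm_anova, summarize_conditions
from .synth import FORCE_RATE_HZ, FatigueProfile, PlantParams, simulate_session
from .trace import Condition, SampledTrace, Task, TrialRecord

__all__ = ["RunManifest", "analyze_session", "run_pipeline", "generate_fixtures"]

logger = logging.getLogger(__name__)

STEP_CHARACTERISTICS = (
    "rise_time_ms",
    "bandwidth_hz",
    "fall_time_ms",
    "overshoot_pct",
    "steady_state_error_pct",
    "steady_state_variability_pct",
)
PULSE_CHARACTERISTICS = ("rise_time_ms", "bandwidth_hz", "fall_time_ms")


@dataclass
class RunManifest:
    """Accounting for one pipeline run; every input trial gets a terminal status."""

    config_hash: str = ""
    n_trials: int = 0
    n_processed: int = 0
    n_failed: int = 0
    trial_status: dict = field(default_factory=dict)   # key -> "ok" | "error: ..."
    exclusion_tally: dict = field(default_factory=dict)
    n_segments: int = 0
    n_excluded: int = 0
    outputs: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "n_trials": self.n_trials,
            "n_processed": self.n_processed,
            "n_failed": self.n_failed,
            "n_segments": self.n_segments,
            "n_excluded": self.n_excluded,
            "exclusion_tally": dict(sorted(self.exclusion_tally.items())),
            "trial_status": {"|".join(map(str, k)): v for k, v in sorted(self.trial_status.items())},
            "outputs": list(self.outputs),
        }


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config_mod.to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _measure_response_trial(trial: TrialRecord, config: AnalysisConfig) -> list[dict]:
    """Filter, segment, screen, and measure one STEP or PULSE trial."""
    filtered = filter_force(trial.force, config=config.force_filter)
    if trial.task is Task.STEP:
        segments = segment_step_task(trial, force=filtered)
        screen = apply_step_exclusions
    else:
        segments = segment_pulse_task(trial, force=filtered)
        screen = apply_pulse_exclusions
    rows = []
    for seg in segments:
        flags = screen(seg, config.exclusion)
        m = compute_step_metrics(seg, config.metrics)
        row = {
            "participant_id": seg.participant_id,
            "condition": seg.condition.value,
            "task": seg.task.value,
            "repetition": seg.repetition,
            "step_index": seg.step_index,
            "excluded": flags.excluded,
            "exclusion_reasons": ";".join(flags.reasons),
        }
        row.update(m.as_dict())
        rows.append(row)
    return rows


def _hold_mdf_rows(trial: TrialRecord, config: AnalysisConfig) -> list[dict]:
    emg = filter_emg(correct_sensor_delay(trial.emg, config.emg_filter.sensor_delay_s),
                     config.emg_filter)
    rows = []
    for name in emg.names:
        series = mdf_time_series(emg[name], config.emg, name=name)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "condition": trial.condition.value,
                "repetition": trial.repetition,
                "channel": name,
                "series": series,
            }
        )
    return rows


def analyze_session(
    trials: list[TrialRecord],
    config: AnalysisConfig | None = None,
    manifest: RunManifest | None = None,
) -> dict:
    """Run the full analysis over one cohort of trials.

    Returns a dict of DataFrames: per-segment ``step_metrics`` and
    ``pulse_metrics``; per-trial ``mvc`` and ``hold_cv``; per-channel
    ``mdf_change``; participant x condition ``summaries``; ``anova`` and
    ``pairwise`` tables for the step characteristics, MVC force, and hold
    variability; and the Pre-Fatigue vs Fatigue-3 ``pulse_comparison``.
    Trials that fail are logged in the manifest and skipped.
    """
    cfg = (config or default_config()).validate()
    man = manifest if manifest is not None else RunManifest()
    man.config_hash = _config_hash(cfg)
    man.n_trials = len(trials)

    step_rows: list[dict] = []
    pulse_rows: list[dict] = []
    mvc_rows: list[dict] = []
    hold_rows: list[dict] = []
    mdf_raw: list[dict] = []

    for trial in trials:
        try:
            if trial.task in (Task.STEP, Task.PULSE):
                rows = _measure_response_trial(trial, cfg)
                (step_rows if trial.task is Task.STEP else pulse_rows).extend(rows)
            elif trial.task is Task.MVC:
                m = mvc_mean(filter_force(trial.force, config=cfg.force_filter), cfg.metrics)
                mvc_rows.append(
                    {
                        "participant_id": trial.participant_id,
                        "condition": trial.condition.value,
                        "repetition": trial.repetition,
                        "mean_force_bw": np.nan if m is None else m.mean_force_bw,
                    }
                )
            elif trial.task is Task.HOLD:
                hm = hold_variability(filter_force(trial.force, config=cfg.force_filter), cfg.metrics)
                hold_rows.append(
                    {
                        "participant_id": trial.participant_id,
                        "condition": trial.condition.value,
                        "repetition": trial.repetition,
                        "final10_mean_cv_pct": np.nan if hm is None else hm.final10_mean_cv_pct,
                        "n_segments": 0 if hm is None else hm.cv_per_second_pct.size,
                    }
                )
                if trial.emg is not None:
                    mdf_raw.extend(_hold_mdf_rows(trial, cfg))
            man.trial_status[trial.key] = "ok"
            man.n_processed += 1
        except Exception as exc:  # noqa: BLE001 - per-trial fault isolation
            logger.warning("trial %s failed: %s", trial.key, exc)
            man.trial_status[trial.key] = f"error: {exc}"
            man.n_failed += 1

    step_df = pd.DataFrame(step_rows, columns=list(METRIC_COLUMNS))
    pulse_df = pd.DataFrame(pulse_rows, columns=list(METRIC_COLUMNS))
    mvc_df = pd.DataFrame(mvc_rows, columns=["participant_id", "condition", "repetition", "mean_force_bw"])
    hold_df = pd.DataFrame(
        hold_rows,
        columns=["participant_id", "condition", "repetition", "final10_mean_cv_pct", "n_segments"],
    )

    for df in (step_df, pulse_df):
        if len(df):
            man.n_segments += int(len(df))
            man.n_excluded += int(df["excluded"].sum())
            for reasons in df.loc[df["excluded"], "exclusion_reasons"]:
                for r in str(reasons).split(";"):
                    if r:
                        man.exclusion_tally[r] = man.exclusion_tally.get(r, 0) + 1

    mdf_df = _mdf_change_table(mdf_raw, cfg)

    # --- condition summaries and inference --------------------------------
    summaries = []
    anova_rows = []
    pairwise_rows = []
    if len(step_df):
        for metric in STEP_CHARACTERISTICS:
            summ = summarize_conditions(step_df, metric, cfg.stats)
            summaries.append(summ)
            try:
                res = rm_anova(summ, metric, config=cfg.stats)
            except ValueError:
                continue
            anova_rows.append(
                {"metric": metric, "measure": "step", "F": res.f_stat, "df_num": res.df_num,
                 "df_den": res.df_den, "p": res.p_value, "n": res.n_subjects,
                 "significant": res.p_value < cfg.stats.alpha}
            )
            if res.p_value < cfg.stats.alpha:
                for pw in bonferroni_pairwise(summ, metric, config=cfg.stats):
                    pairwise_rows.append(
                        {"metric": metric, "measure": "step", "condition_a": pw.condition_a,
                         "condition_b": pw.condition_b, "mean_diff": pw.mean_diff,
                         "p_raw": pw.p_raw, "p_bonferroni": pw.p_bonferroni,
                         "cohens_d": pw.cohens_d, "degenerate": pw.degenerate}
                    )

    # MVC: final MVC per condition is the fatigue measure
    if len(mvc_df):
        final_mvc = (
            mvc_df.sort_values(["participant_id", "condition", "repetition"], kind="mergesort")
            .groupby(["participant_id", "condition"], sort=True)
            .tail(1)
            .rename(columns={"mean_force_bw": "value"})
        )
        final_mvc = final_mvc.assign(metric="mvc_mean_bw")[["participant_id", "condition", "metric", "value"]]
        final_mvc["n_used"] = 1
        final_mvc["short"] = False
        summaries.append(final_mvc)
        try:
            res = rm_anova(final_mvc, "mvc_mean_bw", config=cfg.stats)
            anova_rows.append(
                {"metric": "mvc_mean_bw", "measure": "mvc", "F": res.f_stat, "df_num": res.df_num,
                 "df_den": res.df_den, "p": res.p_value, "n": res.n_subjects,
                 "significant": res.p_value < cfg.stats.alpha}
            )
            if res.p_value < cfg.stats.alpha:
                for pw in bonferroni_pairwise(final_mvc, "mvc_mean_bw", config=cfg.stats):
                    pairwise_rows.append(
                        {"metric": "mvc_mean_bw", "measure": "mvc", "condition_a": pw.condition_a,
                         "condition_b": pw.condition_b, "mean_diff": pw.mean_diff,
                         "p_raw": pw.p_raw, "p_bonferroni": pw.p_bonferroni,
                         "cohens_d": pw.cohens_d, "degenerate": pw.degenerate}
                    )
        except ValueError:
            pass

    # Hold variability: participant x condition mean of the final-10-s CV
    if len(hold_df):
        hold_summary = (
            hold_df.groupby(["participant_id", "condition"], sort=True)["final10_mean_cv_pct"]
            .mean()
            .reset_index()
            .rename(columns={"final10_mean_cv_pct": "value"})
        )
        hold_summary["metric"] = "hold_cv_pct"
        hold_summary["n_used"] = 1
        hold_summary["short"] = False
        summaries.append(hold_summary[["participant_id", "condition", "metric", "value", "n_used", "short"]])
        hold_conditions = [
            c.value for c in (Condition.PRE_FATIGUE, Condition.FATIGUE_1,
                              Condition.FATIGUE_2, Condition.FATIGUE_3)
            if c.value in set(hold_summary["condition"])
        ]
        if len(hold_conditions) >= 2:
            try:
                res = rm_anova(hold_summary, "hold_cv_pct", conditions=hold_conditions, config=cfg.stats)
                anova_rows.append(
                    {"metric": "hold_cv_pct", "measure": "hold", "F": res.f_stat, "df_num": res.df_num,
                     "df_den": res.df_den, "p": res.p_value, "n": res.n_subjects,
                     "significant": res.p_value < cfg.stats.alpha}
                )
            except ValueError:
                pass

    summaries_df = (
        pd.concat(summaries, ignore_index=True)
        if summaries
        else pd.DataFrame(columns=["participant_id", "condition", "metric", "value", "n_used", "short"])
    )

    pulse_cmp = _pulse_comparison(pulse_df, cfg)

    return {
        "step_metrics": step_df,
        "pulse_metrics": pulse_df,
        "mvc": mvc_df,
        "hold_cv": hold_df,
        "mdf_change": mdf_df,
        "summaries": summaries_df,
        "anova": pd.DataFrame(anova_rows),
        "pairwise": pd.DataFrame(pairwise_rows),
        "pulse_comparison": pulse_cmp,
        "manifest": man,
    }


def _mdf_change_table(mdf_raw: list[dict], cfg: AnalysisConfig) -> pd.DataFrame:
    """Baseline (first fatigue hold, first 10 s) vs each condition's last hold."""
    cols = ["participant_id", "condition", "channel", "baseline_hz", "final_hz", "change_pct"]
    if not mdf_raw:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(mdf_raw)
    k = max(1, int(round(cfg.emg.baseline_window_s / cfg.emg.window_s)))
    rows = []
    for (pid, channel), grp in df.groupby(["participant_id", "channel"], sort=True):
        fat = grp[grp["condition"] != Condition.PRE_FATIGUE.value]
        if not len(fat):
            continue
        fat = fat.sort_values(["condition", "repetition"], kind="mergesort")
        base = fat.iloc[0]["series"]
        if base.n < k:
            continue
        base_hz = float(np.nanmean(base.mdf_hz[:k]))
        for cond, cgrp in fat.groupby("condition", sort=True):
            final = cgrp.iloc[-1]["series"]
            change = mdf_fatigue_change(base, final, cfg.emg)
            if change is None:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "channel": channel,
                    "baseline_hz": base_hz,
                    "final_hz": float(np.nanmean(final.mdf_hz[-k:])),
                    "change_pct": change,
                }
            )
    return pd.DataFrame(rows, columns=cols)


def _pulse_comparison(pulse_df: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Pre-Fatigue vs Fatigue-3 paired comparison of pulse responsiveness."""
    cols = ["metric", "mean_pre", "sd_pre", "mean_post", "sd_post", "mean_diff", "p", "cohens_d", "n"]
    if not len(pulse_df):
        return pd.DataFrame(columns=cols)
    from scipy import stats as spstats

    rows = []
    for metric in PULSE_CHARACTERISTICS:
        summ = summarize_conditions(pulse_df, metric, cfg.stats)
        wide = summ.pivot(index="participant_id", columns="condition", values="value")
        pre_c, post_c = Condition.PRE_FATIGUE.value, Condition.FATIGUE_3.value
        if pre_c not in wide.columns or post_c not in wide.columns:
            continue
        wide = wide[[pre_c, post_c]].dropna()
        if len(wide) < 2:
            continue
        a, b = wide[pre_c].to_numpy(), wide[post_c].to_numpy()
        t = spstats.ttest_rel(a, b)
        d = cohens_d(float(a.mean()), float(a.std(ddof=1)), float(b.mean()), float(b.std(ddof=1)))
        rows.append(
            {"metric": metric, "mean_pre": float(a.mean()), "sd_pre": float(a.std(ddof=1)),
             "mean_post": float(b.mean()), "sd_post": float(b.std(ddof=1)),
             "mean_diff": float((a - b).mean()), "p": float(t.pvalue),
             "cohens_d": np.nan if d is None else d, "n": int(len(wide))}
        )
    return pd.DataFrame(rows, columns=cols)


def session_effect_estimates(results: dict) -> dict:
    """Fatigue-effect estimates and operating point from analyzed results.

    Summarizes one cohort's analysis as the quantities the fatigue protocol
    is designed to move: the Pre-Fatigue operating point (MVC force, step
    rise time and bandwidth, hold CV, overshoot, pulse rise time) and the
    Fatigue-3 / Pre-Fatigue effect estimates (percent MVC drop, rise-time
    ratio, hold-CV ratio, gastrocnemius lateralis MDF drop), plus the
    omnibus rise-time ANOVA p-value.  Effects are participant-paired
    (mean of within-participant ratios).
    """
    summ = results["summaries"]
    pre, f3 = Condition.PRE_FATIGUE.value, Condition.FATIGUE_3.value

    def cond_mean(metric: str, cond: str) -> float:
        sel = summ[(summ["metric"] == metric) & (summ["condition"] == cond)]
        return float(sel["value"].mean()) if len(sel) else np.nan

    def paired_ratio(metric: str) -> float:
        sel = summ[summ["metric"] == metric]
        if not len(sel):
            return np.nan
        wide = sel.pivot(index="participant_id", columns="condition", values="value")
        if pre not in wide.columns or f3 not in wide.columns:
            return np.nan
        return float((wide[f3] / wide[pre]).mean())

    mdf = results["mdf_change"]
    gl = mdf[(mdf["channel"] == "gastroc_lateralis") & (mdf["condition"] == f3)]
    anova = results["anova"]
    rise_row = anova[anova["metric"] == "rise_time_ms"] if len(anova) else anova
    pulse = results["pulse_comparison"]
    pulse_rise = pulse[pulse["metric"] == "rise_time_ms"] if len(pulse) else pulse

    return {
        "pre_mvc_bw": cond_mean("mvc_mean_bw", pre),
        "pre_rise_time_ms": cond_mean("rise_time_ms", pre),
        "pre_bandwidth_hz": cond_mean("bandwidth_hz", pre),
        "pre_hold_cv_pct": cond_mean("hold_cv_pct", pre),
        "pre_overshoot_pct": cond_mean("overshoot_pct", pre),
        "pre_pulse_rise_ms": float(pulse_rise["mean_pre"].iloc[0]) if len(pulse_rise) else np.nan,
        "mvc_drop_pct": 100.0 * (1.0 - paired_ratio("mvc_mean_bw")),
        "rise_time_ratio": paired_ratio("rise_time_ms"),
        "hold_cv_ratio": paired_ratio("hold_cv_pct"),
        "mdf_drop_pct": float(gl["change_pct"].mean()) if len(gl) else np.nan,
        "rise_anova_p": float(rise_row["p"].iloc[0]) if len(rise_row) else np.nan,
        "n_excluded": int(results["manifest"].n_excluded),
        "n_segments": int(results["manifest"].n_segments),
    }


# ---------------------------------------------------------------------------
# Disk-level driver
# ---------------------------------------------------------------------------


def _load_trials(input_dir: Path, manifest: RunManifest) -> list[TrialRecord]:
    trials = []
    for path in sorted(input_dir.glob("*.csv")):
        if path.name.endswith(".emg.csv") or path.name.endswith(".meta.json"):
            continue
        try:
            trials.append(read_trial(path))
        except Exception as exc:  # noqa: BLE001
            logger.warning("could not read %s: %s", path.name, exc)
            manifest.trial_status[(path.name, "", "", 0)] = f"error: {exc}"
            manifest.n_failed += 1
            manifest.n_trials += 1
    return trials


def run_pipeline(
    config: AnalysisConfig | None = None,
    *,
    input_dir: str | Path | None = None,
    out_dir: str | Path = "results",
    seed: int = 0,
    n_participants: int = 18,
    emg_policy: str = "holds",
    plant: PlantParams | None = None,
    profile: FatigueProfile | None = None,
) -> RunManifest:
    """Run the whole pipeline and write result tables under ``out_dir``.

    With ``input_dir`` the trials are read from disk; otherwise a synthetic
    session is simulated with ``seed``.  Outputs are deterministic for a
    fixed config and seed: rerunning produces byte-identical tables.
    """
    cfg = (config or default_config()).validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("legforce")
    root.addHandler(log_handler)
    try:
        manifest = RunManifest()
        n_unreadable = 0
        if input_dir is not None:
            trials = _load_trials(Path(input_dir), manifest)
            n_unreadable = manifest.n_failed
        else:
            trials = simulate_session(
                plant, profile, seed, n_participants=n_participants, emg_policy=emg_policy
            )
        results = analyze_session(trials, cfg, manifest)
        # analyze_session counts only the trials it received; add back files
        # that never parsed so every input appears exactly once.
        manifest.n_trials += n_unreadable

        write_metrics_table(results["step_metrics"], out / "step_metrics.csv")
        write_metrics_table(results["pulse_metrics"], out / "pulse_metrics.csv")
        for name in ("mvc", "hold_cv", "mdf_change", "summaries", "anova", "pairwise", "pulse_comparison"):
            results[name].to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        manifest.outputs = sorted(p.name for p in out.glob("*.csv"))
        (out / "manifest.json").write_text(json.dumps(manifest.as_dict(), indent=1))
        return manifest
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def _adversarial_trial(kind: str, seed: int = 0) -> TrialRecord:
    """A single-response trial engineered to fire exactly one criterion."""
    fs = FORCE_RATE_HZ
    task = Task.PULSE if kind.startswith("pulse_") else Task.STEP
    baseline, step = 1.0, 0.4
    upper = baseline + step
    if task is Task.STEP:
        onset, on_s, total = 2.0, 4.0, 8.0
    else:
        onset, on_s, total = 2.0, 0.05, 5.0
    n = int(round(total * fs))
    t = np.arange(n) / fs
    target = np.where((t >= onset) & (t < onset + on_s), upper, baseline)

    def smooth_step(t_arr, t_on, t_off, rise=0.12):
        up = np.clip((t_arr - t_on) / rise, 0, 1)
        down = np.clip((t_off - t_arr) / rise, 0, 1)
        return np.minimum(up, down)

    stepdown = onset + on_s
    if kind == "step_early_rise":
        # the whole response starts 0.7 s early and stays up; necessarily
        # also elevates the pre-onset baseline window
        force = baseline + step * smooth_step(t, onset - 0.7, stepdown + 0.3)
    elif kind == "step_no_rise":
        force = baseline + step * smooth_step(t, onset + 0.7, stepdown + 0.3)
    elif kind == "step_elevated_baseline":
        force = baseline + step * smooth_step(t, onset, stepdown + 0.3)
        lift = 0.15 * step * smooth_step(t, onset - 0.42, onset - 0.02, rise=0.03)
        force = np.maximum(force, baseline + lift)
    elif kind == "step_early_fall":
        force = baseline + step * smooth_step(t, onset, stepdown - 1.3)
    elif kind == "pulse_early_rise":
        force = baseline + step * smooth_step(t, onset - 0.35, stepdown + 0.25, rise=0.08)
    elif kind == "pulse_late_fall":
        force = baseline + step * smooth_step(t, onset, stepdown + 0.75, rise=0.08)
    elif kind == "pulse_clean":
        force = baseline + step * smooth_step(t, onset, stepdown + 0.25, rise=0.08)
    elif kind == "step_clean":
        force = baseline + step * smooth_step(t, onset, stepdown + 0.3)
    else:
        raise ValueError(f"unknown adversarial kind {kind!r}")

    spec_total = total
    return TrialRecord(
        participant_id="ADV",
        condition=Condition.PRE_FATIGUE,
        task=task,
        repetition=1,
        body_weight_n=726.0,
        force=SampledTrace(force, fs),
        target=SampledTrace(target, fs),
        onsets_s=(onset,),
        on_duration_s=on_s,
        meta={"adversarial": kind, "total_s": spec_total, "seed": seed},
    )


ADVERSARIAL_KINDS = (
    "step_early_rise",
    "step_no_rise",
    "step_elevated_baseline",
    "step_early_fall",
    "pulse_early_rise",
    "pulse_late_fall",
)


def generate_fixtures(seed: int, out_dir: str | Path, *, n_participants: int = 2,
                      emg_policy: str = "endpoints") -> list[Path]:
    """Write a miniature synthetic study plus one trial per exclusion reason.

    Regeneration with the same seed produces identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    trials = simulate_session(seed=seed, n_participants=n_participants, emg_policy=emg_policy)
    for trial in trials:
        stem = "_".join(map(str, trial.key))
        paths.append(write_trial(trial, out / f"{stem}.csv"))
    for kind in ADVERSARIAL_KINDS:
        paths.append(write_trial(_adversarial_trial(kind, seed), out / f"adversarial_{kind}.csv"))
    return paths
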