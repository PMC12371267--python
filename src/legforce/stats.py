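"""Condition-level aggregation and inference.

Each participant contributes, per condition, the mean of a metric over the
first five non-excluded step responses recorded immediately after the
condition's final MVC.  Condition means are compared with a one-way
repeated-measures ANOVA (classical within-subject decomposition,
F = MS_condition / MS_(condition x subject)); significant omnibus effects
are followed by paired t-tests over all C(5,2) = 10 condition pairs with
Bonferroni correction, and effect sizes are pooled-SD Cohen's d.  The pulse
task is compared Pre-Fatigue vs Fatigue-3 only, by paired t-test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .config import AnalysisConfig, StatsConfig
from .trace import Condition

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "summarize_conditions",
    "rm_anova",
    "bonferroni_pairwise",
    "cohens_d",
    "effect_size_label",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    metric: str
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    n_subjects: int
    gg_epsilon: float | None = None  # Greenhouse-Geisser, when correction is on


@dataclass(frozen=True)
class PairwiseResult:
    metric: str
    condition_a: str
    condition_b: str
    mean_diff: float
    p_raw: float
    p_bonferroni: float
    cohens_d: float
    degenerate: bool = False


def _stats_cfg(config: AnalysisConfig | StatsConfig | None) -> StatsConfig:
    if config is None:
        return StatsConfig()
    if isinstance(config, AnalysisConfig):
        return config.stats
    return config


def summarize_conditions(
    metric_rows: pd.DataFrame,
    metric: str,
    config: AnalysisConfig | StatsConfig | None = None,
) -> pd.DataFrame:
    """Participant x condition means over the first five usable responses.

    ``metric_rows`` is the per-segment table (one row per response, with
    ``excluded`` flags and trial-order columns ``repetition`` and
    ``step_index``).  For each participant x condition the first
    ``first_n_responses`` non-excluded responses *in trial order* are
    averaged; cells with fewer are averaged over what exists and flagged
    (``n_used``); cells with none are omitted.  Output is invariant to the
    ordering of input rows.
    """
    cfg = _stats_cfg(config)
    required = {"participant_id", "condition", "repetition", "step_index", "excluded", metric}
    missing = required - set(metric_rows.columns)
    if missing:
        raise ValueError(f"metric table missing column(s): {sorted(missing)}")

    rows = []
    grouped = metric_rows.sort_values(["repetition", "step_index"], kind="mergesort").groupby(
        ["participant_id", "condition"], sort=True
    )
    for (pid, cond), grp in grouped:
        usable = grp[~grp["excluded"].astype(bool) & grp[metric].notna()]
        head = usable.head(cfg.first_n_responses)
        if len(head) == 0:
            continue
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "metric": metric,
                "value": float(head[metric].mean()),
                "n_used": int(len(head)),
                "short": len(head) < cfg.first_n_responses,
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "condition", "metric", "value", "n_used", "short"])


def _wide(summary: pd.DataFrame, conditions: list[str] | None) -> pd.DataFrame:
    wide = summary.pivot(index="participant_id", columns="condition", values="value")
    if conditions is None:
        conditions = [c.value for c in Condition.ordered() if c.value in wide.columns]
    wide = wide[conditions]
    complete = wide.dropna()
    dropped = set(wide.index) - set(complete.index)
    if dropped:
        logger.warning("rm_anova: dropping incomplete participant(s): %s", sorted(dropped))
    return complete


def rm_anova(
    summary: pd.DataFrame,
    metric: str | None = None,
    conditions: list[str] | None = None,
    config: AnalysisConfig | StatsConfig | None = None,
) -> AnovaResult:
    """One-way repeated-measures ANOVA across conditions.

    Classical decomposition: with k conditions and n complete participants,
    F = MS_condition / MS_(condition x subject) on (k-1, (k-1)(n-1)) df.
    Degenerate tables (no condition variance) return F = 0, p = 1.
    Greenhouse-Geisser correction is applied when the config enables it.
    """
    cfg = _stats_cfg(config)
    if metric is not None and "metric" in summary.columns:
        summary = summary[summary["metric"] == metric]
    name = metric or (summary["metric"].iloc[0] if "metric" in summary.columns and len(summary) else "")
    wide = _wide(summary, conditions)
    n, k = wide.shape
    if n < 2 or k < 2:
        raise ValueError(f"rm_anova needs >= 2 complete participants and >= 2 conditions, got {n} x {k}")

    x = wide.to_numpy(dtype=float)
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_num, df_den = k - 1, (k - 1) * (n - 1)

    scale = max(ss_total, 1.0)
    if ss_cond / scale < 1e-14:
        return AnovaResult(name, 0.0, df_num, df_den, 1.0, n)
    if ss_err / scale < 1e-14:
        return AnovaResult(name, math.inf, df_num, df_den, 0.0, n)

    f_stat = (ss_cond / df_num) / (ss_err / df_den)
    eps = None
    d_num, d_den = float(df_num), float(df_den)
    if cfg.sphericity_correction:
        eps = _gg_epsilon(x)
        d_num, d_den = eps * df_num, eps * df_den
    p = float(spstats.f.sf(f_stat, d_num, d_den))
    return AnovaResult(name, float(f_stat), df_num, df_den, p, n, gg_epsilon=eps)


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float | None:
    """Pooled-SD effect size: (mean1 - mean2) / sqrt((sd1^2 + sd2^2) / 2)."""
    pooled = math.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0:
        return None
    return (mean1 - mean2) / pooled


def effect_size_label(d: float) -> str:
    """Conventional qualitative bands: small ~0.2, medium ~0.5, large > 0.8."""
    a = abs(d)
    if a > 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def bonferroni_pairwise(
    summary: pd.DataFrame,
    metric: str | None = None,
    conditions: list[str] | None = None,
    config: AnalysisConfig | StatsConfig | None = None,
    n_comparisons: int | None = None,
) -> list[PairwiseResult]:
    """Paired two-sided t-tests over all condition pairs, Bonferroni-corrected.

    The correction factor is the number of pairs tested (10 for five
    conditions); corrected p-values are capped at 1 and never fall below
    the raw p.  Zero-variance difference vectors are degenerate: p is 1
    when the means agree exactly, 0 otherwise, and the result is flagged.
    """
    if metric is not None and "metric" in summary.columns:
        summary = summary[summary["metric"] == metric]
    name = metric or (summary["metric"].iloc[0] if "metric" in summary.columns and len(summary) else "")
    wide = _wide(summary, conditions)
    conds = list(wide.columns)
    pairs = list(itertools.combinations(conds, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)

    results = []
    for ca, cb in pairs:
        a = wide[ca].to_numpy(dtype=float)
        b = wide[cb].to_numpy(dtype=float)
        diff = a - b
        mean_diff = float(diff.mean())
        d = cohens_d(float(a.mean()), float(a.std(ddof=1)), float(b.mean()), float(b.std(ddof=1)))
        if np.allclose(diff, diff[0]):
            degenerate = True
            p_raw = 1.0 if abs(mean_diff) < 1e-12 else 0.0
        else:
            degenerate = False
            p_raw = float(spstats.ttest_rel(a, b).pvalue)
        results.append(
            PairwiseResult(
                metric=name,
                condition_a=ca,
                condition_b=cb,
                mean_diff=mean_diff,
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * m),
                cohens_d=math.nan if d is None else d,
                degenerate=degenerate,
            )
        )
    return results
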