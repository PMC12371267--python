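"""Condition summaries and inference against hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from legforce.config import StatsConfig
from legforce.stats import (
    bonferroni_pairwise,
    cohens_d,
    effect_size_label,
    rm_anova,
    summarize_conditions,
)

CONDITIONS = ["Training", "PreFatigue", "Fatigue1", "Fatigue2", "Fatigue3"]


def metric_rows(values_by_pid, condition="PreFatigue", excluded=None, metric="rise_time_ms"):
    """Per-response rows: values_by_pid maps pid -> list of response values."""
    rows = []
    for pid, values in values_by_pid.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "participant_id": pid,
                    "condition": condition,
                    "repetition": 1 + i // 10,
                    "step_index": i % 10,
                    "excluded": bool(excluded and (pid, i) in excluded),
                    metric: v,
                }
            )
    return pd.DataFrame(rows)


def summary_from_wide(wide: dict, metric="m") -> pd.DataFrame:
    rows = []
    for pid, per_cond in wide.items():
        for cond, val in per_cond.items():
            rows.append({"participant_id": pid, "condition": cond, "metric": metric,
                         "value": val, "n_used": 5, "short": False})
    return pd.DataFrame(rows)


class TestSummaries:
    def test_first_five_of_ten_unexcluded(self):
        df = metric_rows({"P01": list(range(10))})
        out = summarize_conditions(df, "rise_time_ms")
        assert out.loc[0, "value"] == pytest.approx(np.mean([0, 1, 2, 3, 4]))
        assert out.loc[0, "n_used"] == 5 and not out.loc[0, "short"]

    def test_exclusions_shift_the_window(self):
        """Responses 2 and 4 excluded: the mean covers 1,3,5,6,7 (1-indexed)."""
        df = metric_rows({"P01": list(range(1, 11))}, excluded={("P01", 1), ("P01", 3)})
        out = summarize_conditions(df, "rise_time_ms")
        assert out.loc[0, "value"] == pytest.approx(np.mean([1, 3, 5, 6, 7]))

    def test_all_excluded_gives_missing_cell(self):
        df = metric_rows({"P01": [1.0, 2.0]}, excluded={("P01", 0), ("P01", 1)})
        out = summarize_conditions(df, "rise_time_ms")
        assert len(out) == 0

    def test_fewer_than_five_flagged_short(self):
        df = metric_rows({"P01": [1.0, 2.0, 3.0]})
        out = summarize_conditions(df, "rise_time_ms")
        assert out.loc[0, "n_used"] == 3 and bool(out.loc[0, "short"])

    def test_invariant_to_row_order(self):
        df = metric_rows({"P01": list(range(10)), "P02": list(range(10, 20))})
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = summarize_conditions(df, "rise_time_ms")
        b = summarize_conditions(shuffled, "rise_time_ms")
        pd.testing.assert_frame_equal(a, b)


class TestRmAnova:
    def test_identical_conditions_give_f_zero_p_one(self):
        wide = {f"P{i}": {c: 10.0 + i for c in CONDITIONS} for i in range(4)}
        res = rm_anova(summary_from_wide(wide), "m")
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_toy_table_matches_hand_computed_sums_of_squares(self):
        """3x3 table: SS_cond = 366/27, SS_err = 10/9 -> F = 24.4 on (2, 4) df."""
        wide = {
            "P1": {"A": 1.0, "B": 2.0, "C": 3.0},
            "P2": {"A": 2.0, "B": 3.0, "C": 5.0},
            "P3": {"A": 3.0, "B": 5.0, "C": 7.0},
        }
        res = rm_anova(summary_from_wide(wide), "m", conditions=["A", "B", "C"])
        assert res.f_stat == pytest.approx(24.4, abs=1e-9)
        assert (res.df_num, res.df_den) == (2, 4)
        assert res.p_value == pytest.approx(float(spstats.f.sf(24.4, 2, 4)), rel=1e-9)

    def test_matches_statsmodels_anova_rm(self):
        """Independent oracle: statsmodels AnovaRM on a random table."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(8)
        long = []
        for pid in range(10):
            base = rng.normal(300, 40)
            for j, cond in enumerate(CONDITIONS):
                long.append({"pid": pid, "cond": cond, "y": base + 5 * j + rng.normal(0, 10)})
        df = pd.DataFrame(long)
        sm_res = AnovaRM(df, "y", "pid", within=["cond"]).fit()
        f_sm = float(sm_res.anova_table["F Value"].iloc[0])
        p_sm = float(sm_res.anova_table["Pr > F"].iloc[0])

        wide = {
            f"P{pid}": {row["cond"]: row["y"] for _, row in grp.iterrows()}
            for pid, grp in df.groupby("pid")
        }
        res = rm_anova(summary_from_wide(wide), "m", conditions=CONDITIONS)
        assert res.f_stat == pytest.approx(f_sm, rel=1e-9)
        assert res.p_value == pytest.approx(p_sm, rel=1e-9)

    def test_incomplete_participants_dropped(self, caplog):
        wide = {f"P{i}": {c: float(i) + j for j, c in enumerate(CONDITIONS)} for i in range(5)}
        wide["P9"] = {"Training": 1.0}  # missing four cells
        res = rm_anova(summary_from_wide(wide), "m", conditions=CONDITIONS)
        assert res.n_subjects == 5

    def test_too_few_participants_error(self):
        wide = {"P1": {"A": 1.0, "B": 2.0}}
        with pytest.raises(ValueError, match="complete participants"):
            rm_anova(summary_from_wide(wide), "m", conditions=["A", "B"])

    def test_type_one_error_calibrated_under_null(self):
        """Additive subject offsets, no condition effect: ~5% rejections."""
        rng = np.random.default_rng(123)
        n_tables, n, k = 2000, 10, 5
        rejections = 0
        for _ in range(n_tables):
            x = rng.normal(0, 5, (n, 1)) + rng.normal(0, 1, (n, k))
            wide = {f"P{i}": dict(zip(CONDITIONS, x[i])) for i in range(n)}
            res = rm_anova(summary_from_wide(wide), "m", conditions=CONDITIONS)
            rejections += res.p_value < 0.05
        rate = rejections / n_tables
        assert 0.035 <= rate <= 0.065

    def test_label_thresholds(self):
        assert effect_size_label(0.1) == "negligible"
        assert effect_size_label(0.3) == "small"
        assert effect_size_label(-0.6) == "medium"
        assert effect_size_label(1.4) == "large"


class TestPairwise:
    def test_identical_conditions_give_corrected_p_one(self):
        wide = {f"P{i}": {"A": 1.0 + i, "B": 1.0 + i} for i in range(5)}
        (res,) = bonferroni_pairwise(summary_from_wide(wide), "m", conditions=["A", "B"])
        assert res.p_bonferroni == 1.0 and res.degenerate

    def test_toy_paired_t_matches_hand_computation(self):
        """diffs (-1,-1,-2,0): t = -2.4495 on 3 df, p = 0.0917, x10 corrected."""
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 5.0, 4.0]
        wide = {f"P{i}": {"A": a[i], "B": b[i]} for i in range(4)}
        (res,) = bonferroni_pairwise(
            summary_from_wide(wide), "m", conditions=["A", "B"], n_comparisons=10
        )
        t_hand = -1.0 / (math.sqrt(2.0 / 3.0) / 2.0)
        assert t_hand == pytest.approx(-2.449489742783178)
        assert res.p_raw == pytest.approx(2 * spstats.t.sf(2.449489742783178, 3), rel=1e-9)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p_raw * 10), rel=1e-12)
        assert res.mean_diff == pytest.approx(-1.0)

    def test_five_conditions_give_ten_pairs_and_no_shrinking(self):
        rng = np.random.default_rng(5)
        wide = {
            f"P{i}": {c: float(rng.normal(300, 30)) for c in CONDITIONS} for i in range(8)
        }
        results = bonferroni_pairwise(summary_from_wide(wide), "m", conditions=CONDITIONS)
        assert len(results) == 10
        for r in results:
            assert r.p_bonferroni >= r.p_raw - 1e-15
            assert r.p_bonferroni <= 1.0


class TestCohensD:
    def test_unit_case(self):
        assert cohens_d(1.0, 1.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_mvc_effect_size_magnitude(self):
        """2.95 +/- 0.58 vs 2.20 +/- 0.47 BW is a pooled-SD d of ~1.42."""
        assert cohens_d(2.95, 0.58, 2.20, 0.47) == pytest.approx(1.4208, abs=0.001)

    def test_equal_means_give_zero(self):
        assert cohens_d(2.0, 0.5, 2.0, 0.7) == 0.0

    def test_zero_pooled_sd_uncomputable(self):
        assert cohens_d(1.0, 0.0, 2.0, 0.0) is None
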