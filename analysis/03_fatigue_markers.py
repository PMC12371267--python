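"""Summarize the objective fatigue markers from the analyzed session.

Reads the tables written by 02_run_pipeline.py and reports the three
markers the protocol manipulates: maximal force (MVC mean, final MVC of
each condition), hold-task force steadiness (final-10-s CV), and EMG
median-frequency compression (baseline vs the final fatigue hold).
"""

import sys
from pathlib import Path

import pandas as pd

IN = Path("results/session")
CONDITIONS = ["Training", "PreFatigue", "Fatigue1", "Fatigue2", "Fatigue3"]


def main() -> int:
    summaries = pd.read_csv(IN / "summaries.csv")
    mdf = pd.read_csv(IN / "mdf_change.csv")

    mvc = summaries[summaries.metric == "mvc_mean_bw"]
    print("MVC mean force by condition (BW, cohort mean +/- SD):")
    for cond in CONDITIONS:
        v = mvc[mvc.condition == cond]["value"]
        print(f"  {cond:<12s} {v.mean():.3f} +/- {v.std():.3f}")
    wide = mvc.pivot(index="participant_id", columns="condition", values="value")
    drop = 100 * (1 - wide["Fatigue3"] / wide["PreFatigue"])
    print(f"  Pre-Fatigue -> Fatigue-3 decline: {drop.mean():.1f} +/- {drop.std():.1f} %")

    hold = summaries[summaries.metric == "hold_cv_pct"]
    print("\nHold-task force variability (final-10-s CV, %):")
    for cond in [c for c in CONDITIONS if c in set(hold.condition)]:
        v = hold[hold.condition == cond]["value"]
        print(f"  {cond:<12s} {v.mean():.2f} +/- {v.std():.2f}")
    hw = hold.pivot(index="participant_id", columns="condition", values="value")
    print(f"  fold increase Pre-Fatigue -> Fatigue-3: "
          f"{(hw['Fatigue3'] / hw['PreFatigue']).mean():.2f}x")

    f3 = mdf[mdf.condition == "Fatigue3"]
    print("\nEMG median frequency, baseline -> final fatigue hold:")
    for channel, grp in f3.groupby("channel"):
        print(f"  {channel:<20s} {grp.baseline_hz.mean():5.1f} -> {grp.final_hz.mean():5.1f} Hz "
              f"({grp.change_pct.mean():4.1f} +/- {grp.change_pct.std():.1f} % reduction)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
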