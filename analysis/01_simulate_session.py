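"""Simulate the five-condition force-control protocol for one participant
and write the trials to disk as CSV + sidecar files.

The full study cohort is simulated in memory by the later scripts; this one
exists to show (and let you inspect) what the generator produces: per
condition, the MVC / Hold / Step / Pulse trial inventory, and the on-disk
trial format the pipeline consumes.
"""

import sys
from collections import Counter
from pathlib import Path

from legforce.io import write_trial
from legforce.synth import simulate_session

OUT = Path("results/trials_demo")
SEED = 1


def main() -> int:
    trials = simulate_session(seed=SEED, n_participants=1, emg_policy="endpoints")
    OUT.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        write_trial(trial, OUT / ("_".join(map(str, trial.key)) + ".csv"))

    print(f"Simulated 1 participant, seed {SEED}: {len(trials)} trials")
    for cond in ("Training", "PreFatigue", "Fatigue1", "Fatigue2", "Fatigue3"):
        tasks = Counter(t.task.value for t in trials if t.condition.value == cond)
        inventory = ", ".join(f"{n}x {k}" for k, n in sorted(tasks.items()))
        print(f"  {cond:<12s} {inventory}")
    n_emg = sum(1 for t in trials if t.emg is not None)
    print(f"EMG recorded on {n_emg} hold trials (6 channels at 2000 Hz)")
    print(f"Trials written to {OUT}/ (CSV + .meta.json sidecars)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
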