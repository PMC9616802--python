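"""Behavioural summaries and the composite outlier screen.

Simulates behavioural metadata for a cohort (Bernoulli accuracies with the
task presets, lognormal RTs, plus one deliberately poor performer), then
reports per-task accuracy/RT and which participants the 1.5-IQR composite
rule excludes.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from thetawm import behavior, synth  # noqa: E402

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(RESULTS, exist_ok=True)
    rng = np.random.default_rng(11)
    rows = []
    for p in range(30):
        poor = p == 17   # one low performer the screen should flag
        for task, n in (("dms", 180), ("1back", 148), ("2back", 304)):
            p_correct = 0.45 if poor else synth.ACCURACY_PRESETS[task]
            correct = rng.random(n) < p_correct
            rt = synth.RT_MEDIANS[task] * np.exp(
                synth.RT_SIGMA * rng.standard_normal(n))
            rows.append(pd.DataFrame({"participant": f"P{p:02d}",
                                      "task": task, "correct": correct,
                                      "rt": rt}))
    table = pd.concat(rows, ignore_index=True)
    summary = behavior.accuracy_summary(table)
    screen = behavior.exclusion_screen(summary)

    summary.to_csv(os.path.join(RESULTS, "behavior_summary.tsv"),
                   sep="\t", index=False)
    screen.to_csv(os.path.join(RESULTS, "behavior_exclusion.tsv"),
                  sep="\t", index=False)

    by_task = summary.groupby("task")["accuracy"].mean()
    print("mean accuracy by task:")
    for task, acc in by_task.items():
        print(f"  {task}: {acc:.3f}")
    flagged = screen.loc[screen["excluded"], "participant"].tolist()
    print(f"composite 1.5-IQR screen excluded {len(flagged)} of 30: {flagged}")


if __name__ == "__main__":
    main()
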