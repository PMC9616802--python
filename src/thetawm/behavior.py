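"""Behavioural summaries and participant exclusion screening."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import iqr_outliers


def accuracy_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction correct (and mean RT) per participant and task.

    ``table`` needs columns ``participant``, ``task``, ``correct`` and
    optionally ``rt``; RT means use correct trials only.
    """
    rows = []
    for (p, task), g in table.groupby(["participant", "task"]):
        rec = {"participant": p, "task": task,
               "accuracy": float(g["correct"].mean()),
               "n_trials": len(g)}
        if "rt" in g:
            rts = g.loc[g["correct"].astype(bool), "rt"].dropna()
            rec["mean_rt"] = float(rts.mean()) if len(rts) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def exclusion_screen(summary: pd.DataFrame) -> pd.DataFrame:
    """Composite-score outlier screen across participants.

    The composite is the mean accuracy across tasks; a participant is
    flagged when the composite lies more than 1.5 inter-quartile ranges
    outside the quartiles.  Returns one row per participant with the
    composite and an ``excluded`` flag; the flag count is in
    ``.attrs['n_excluded']``.
    """
    composite = (summary.groupby("participant")["accuracy"].mean()
                 .rename("composite").reset_index())
    mask = iqr_outliers(composite["composite"].to_numpy())
    composite["excluded"] = mask
    composite.attrs["n_excluded"] = int(mask.sum())
    return composite
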