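"""Luminescence activity-reporter plate analysis.

Freely behaving flies carrying a luminescence transcriptional reporter of
neuronal activity are read on a 96-well plate reader every 15 min.  Each
plate carries empty wells (no fly) whose mean trace estimates background;
background-corrected traces are normalized by a single scalar — the
time-mean of the pointwise-mean naive trace — so the naive group's grand
mean is exactly 1 and experienced-group deviations read as fold change.
The readout statistic is the per-well mean normalized luminescence over
the 1-3 h post-training window (TP1-3), compared across groups with a
two-sided Student t test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["subtract_background", "normalize", "window_contrast", "TP13_MIN"]

#: TP1-3 in minutes post-training, half-open
TP13_MIN = (60.0, 180.0)


def subtract_background(plate: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean empty-well trace from every well, pointwise.

    ``plate`` is long-format ``well_id, role, t_min, lum`` (extra columns
    pass through), ``role`` in {empty, naive, experienced}.  Requires at
    least one empty well (warns below 3).  Negative corrected values are
    permitted.  Adds a ``lum_corr`` column.
    """
    roles = plate["role"].unique()
    empty = plate[plate["role"] == "empty"]
    if empty["well_id"].nunique() == 0:
        raise ValueError("plate has no empty wells for background estimation")
    if empty["well_id"].nunique() < 3:
        warnings.warn("fewer than 3 empty wells; background estimate is noisy")
    bg = empty.groupby("t_min")["lum"].mean()
    out = plate.copy()
    out["lum_corr"] = out["lum"] - out["t_min"].map(bg)
    if out["lum_corr"].isna().any():
        raise ValueError("sampling grid not shared between wells and empty wells")
    del roles
    return out


def normalize(corrected: pd.DataFrame) -> pd.DataFrame:
    """Normalize background-corrected traces by the naive-group scalar.

    The scalar s is the time-mean of the pointwise mean corrected trace of
    naive wells over the full recorded session; ``nlum = lum_corr / s``.
    By construction the grand mean of naive nlum is exactly 1.  Raises if
    s <= 0 (naive signal at or below background).
    """
    naive = corrected[corrected["role"] == "naive"]
    if naive["well_id"].nunique() == 0:
        raise ValueError("no naive wells to normalize against")
    s = naive.groupby("t_min")["lum_corr"].mean().mean()
    if not s > 0:
        raise ValueError(f"naive normalization scalar {s} <= 0 (signal below background)")
    out = corrected.copy()
    out["nlum"] = out["lum_corr"] / s
    return out


def window_contrast(
    normalized: pd.DataFrame,
    window: tuple[float, float] = TP13_MIN,
    exp_role: str = "experienced",
) -> tuple[pd.DataFrame, dict]:
    """Per-well mean nlum over the window plus an exp-vs-naive t test.

    Samples with ``t_min`` in ``[start, end)`` contribute; on the 15-min
    grid the default TP1-3 window holds exactly 8 samples per well.
    Returns ``(per_well, stats_dict)`` where ``per_well`` has columns
    ``well_id, role, mean_nlum`` and the dict carries the two-sided
    Student t test of experienced vs naive window means.
    """
    start, end = window
    sel = normalized[
        (normalized["t_min"] >= start)
        & (normalized["t_min"] < end)
        & (normalized["role"] != "empty")
    ]
    if len(sel) == 0:
        raise ValueError("no samples inside window")
    per_well = (
        sel.groupby(["well_id", "role"], sort=True)["nlum"]
        .agg(mean_nlum="mean", n_samples="size")
        .reset_index()
    )
    exp_vals = per_well.loc[per_well["role"] == exp_role, "mean_nlum"].to_numpy()
    nai_vals = per_well.loc[per_well["role"] == "naive", "mean_nlum"].to_numpy()
    report: dict = {"window_min": list(window)}
    if exp_vals.size >= 2 and nai_vals.size >= 2:
        t, p = stats.ttest_ind(exp_vals, nai_vals)
        report.update(
            t=float(t),
            p=float(p),
            mean_exp=float(exp_vals.mean()),
            mean_naive=float(nai_vals.mean()),
            n_exp=int(exp_vals.size),
            n_naive=int(nai_vals.size),
        )
    return per_well, report
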