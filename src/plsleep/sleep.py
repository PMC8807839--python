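"""Sleep scoring from locomotion traces.

The pipeline mirrors the standard fly video-tracking analysis: frame-level
displacement (mm, nominally 5 Hz) is pooled into 60-s bins; a minute is
*active* when its total displacement reaches the activity threshold
(default 3.6 mm / 60 s); *sleep* is any maximal run of >= 5 consecutive
inactive minutes; sleep amount is pooled in 30-min bins; per-fly ΔSleep is
the fly's binned sleep minus the mean of a matched control cohort, and the
headline statistic is the mean ΔSleep over the 1-3 h post-training window
(TP1-3).

All times are seconds relative to the end of training (t = 0); minutes and
bins are half-open intervals anchored at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MINUTE_S = 60.0

__all__ = [
    "bin_minutes",
    "score_sleep",
    "pool_sleep",
    "delta_sleep",
    "window_mean",
    "group_tests",
    "activation_delta",
    "GroupTestReport",
]


def _check_trace(trace: pd.DataFrame) -> None:
    if len(trace) == 0:
        raise ValueError("empty locomotion trace")
    for col in ("fly_id", "t_s", "d_mm"):
        if col not in trace.columns:
            raise ValueError(f"locomotion trace missing column {col!r}")
    if (trace["d_mm"] < 0).any():
        raise ValueError("negative displacement in locomotion trace")


def bin_minutes(
    trace: pd.DataFrame,
    threshold_mm: float = 3.6,
    sample_rate: float = 5.0,
    min_frac_present: float = 0.5,
) -> pd.DataFrame:
    """Pool a frame-level locomotion trace into per-minute activity states.

    Parameters
    ----------
    trace
        Long-format frame data with columns ``fly_id``, ``t_s`` (seconds
        relative to end of training, strictly increasing per fly) and
        ``d_mm`` (displacement per frame, >= 0).  A ``condition`` column,
        if present, is carried through.
    threshold_mm
        A minute is active iff its summed displacement is >= this value.
        The boundary is assigned to *active* so that "no locomotion" stays
        strictly sub-threshold.
    sample_rate
        Nominal frame rate in Hz, used to judge completeness.
    min_frac_present
        Minutes with fewer than this fraction of the expected samples are
        flagged invalid (they later break sleep runs rather than extend
        them).

    Returns
    -------
    DataFrame with one row per complete 60-s bin and per fly:
    ``fly_id, minute_start, dist_mm, active, valid`` (plus ``condition``
    when supplied).  Minute bins are ``[minute_start, minute_start + 60)``
    anchored at t = 0; an incomplete trailing bin is dropped.
    """
    _check_trace(trace)
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    expected = sample_rate * MINUTE_S

    out = []
    cond_col = "condition" if "condition" in trace.columns else None
    for fly_id, g in trace.groupby("fly_id", sort=False, observed=True):
        t = g["t_s"].to_numpy(float)
        d = g["d_mm"].to_numpy(float)
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError(f"non-monotone time axis for fly {fly_id!r}")
        minute = np.floor(t / MINUTE_S).astype(np.int64)
        m0, m1 = minute.min(), minute.max()
        # last frame covers one frame interval; the trailing bin is complete
        # only if the trace reaches its end
        coverage_end = t[-1] + 1.0 / sample_rate
        if coverage_end < (m1 + 1) * MINUTE_S - 1e-9:
            keep = minute < m1
            if not keep.any():
                raise ValueError(f"trace for fly {fly_id!r} shorter than one minute")
            minute, d = minute[keep], d[keep]
            m1 -= 1
        idx = minute - m0
        n_bins = m1 - m0 + 1
        dist = np.bincount(idx, weights=d, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        rec = pd.DataFrame(
            {
                "fly_id": fly_id,
                "minute_start": (np.arange(m0, m1 + 1)) * MINUTE_S,
                "dist_mm": dist,
                "active": dist >= threshold_mm,
                "valid": counts >= min_frac_present * expected,
            }
        )
        if cond_col:
            rec[cond_col] = g[cond_col].iloc[0]
        out.append(rec)
    return pd.concat(out, ignore_index=True)


def _sleep_runs(inactive: np.ndarray, min_run: int) -> np.ndarray:
    """Mark minutes inside maximal runs of >= min_run consecutive True."""
    asleep = np.zeros(len(inactive), dtype=bool)
    if len(inactive) == 0:
        return asleep
    padded = np.concatenate(([False], inactive, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            asleep[s:e] = True
    return asleep


def score_sleep(minutes: pd.DataFrame, min_run: int = 5) -> pd.DataFrame:
    """Apply the 5-min immobility rule to a per-minute activity series.

    A minute is asleep iff it lies inside a maximal run of >= ``min_run``
    consecutive inactive minutes.  Invalid minutes break runs (sleep is
    never fabricated across unobserved gaps); runs truncated by the
    recording boundary count only if the observed run already reaches
    ``min_run``.  A gap in the minute grid is an error.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    out = []
    for fly_id, g in minutes.groupby("fly_id", sort=False, observed=True):
        g = g.sort_values("minute_start")
        ms = g["minute_start"].to_numpy(float)
        if len(ms) > 1 and not np.allclose(np.diff(ms), MINUTE_S):
            raise ValueError(f"gap in minute grid for fly {fly_id!r}")
        inactive = (~g["active"].to_numpy(bool)) & g["valid"].to_numpy(bool)
        g = g.copy()
        g["asleep"] = _sleep_runs(inactive, min_run)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def pool_sleep(minutes: pd.DataFrame, bin_min: int = 30) -> pd.DataFrame:
    """Pool scored minutes into sleep amount per ``bin_min``-minute bin.

    Returns ``fly_id, bin_start, sleep_min, n_min, valid``; ``valid`` is
    False for bins containing any invalid minute or fewer than ``bin_min``
    observed minutes.  Bins are ``[bin_start, bin_start + bin_min*60)``
    anchored at t = 0.
    """
    if "asleep" not in minutes.columns:
        raise ValueError("minutes must be scored with score_sleep first")
    bin_s = bin_min * MINUTE_S
    df = minutes.copy()
    df["bin_start"] = np.floor(df["minute_start"] / bin_s) * bin_s
    pooled = (
        df.groupby(["fly_id", "bin_start"], sort=True, observed=True)
        .agg(
            sleep_min=("asleep", "sum"),
            n_min=("asleep", "size"),
            all_valid=("valid", "all"),
        )
        .reset_index()
    )
    pooled["sleep_min"] = pooled["sleep_min"].astype(float)
    pooled["valid"] = pooled["all_valid"] & (pooled["n_min"] == bin_min)
    return pooled.drop(columns="all_valid")


def delta_sleep(
    exp: pd.DataFrame,
    ctrl: pd.DataFrame,
    value_col: str = "sleep_min",
) -> pd.DataFrame:
    """Per-fly ΔSleep: experimental binned sleep minus control cohort mean.

    Both inputs are ``pool_sleep`` outputs on a shared bin grid.  The
    result has ``fly_id, bin_start, delta_min``, defined only on bins
    where the control mean exists.
    """
    ctrl_mean = ctrl.groupby("bin_start")[value_col].mean()
    exp_bins = set(exp["bin_start"].unique())
    common = exp_bins & set(ctrl_mean.index)
    if not common:
        raise ValueError("experimental and control bin grids do not overlap")
    out = exp[exp["bin_start"].isin(common)][["fly_id", "bin_start", value_col]].copy()
    out["delta_min"] = out[value_col] - out["bin_start"].map(ctrl_mean)
    return out.drop(columns=value_col)


def window_mean(
    series: pd.DataFrame,
    window: tuple[float, float],
    value_col: str = "delta_min",
) -> pd.Series:
    """Per-fly mean of a binned series over bins with bin_start in [start, end).

    The default TP1-3 window is ``(3600, 10800)`` seconds, which on a
    30-min grid selects the bins starting at 60, 90, 120 and 150 min.
    """
    start, end = window
    if not start < end:
        raise ValueError("window start must be < end")
    sel = series[(series["bin_start"] >= start) & (series["bin_start"] < end)]
    if len(sel) == 0:
        raise ValueError("no bins inside window")
    return sel.groupby("fly_id", observed=True)[value_col].mean()


TP13_S = (3600.0, 10800.0)


@dataclass
class GroupTestReport:
    """Signed-rank p per group (H0: median = 0) and rank-sum p per pair."""

    signed_rank: dict
    rank_sum: dict
    flags: dict


def _signed_rank_zero(x: np.ndarray) -> tuple[float, str]:
    x = np.asarray(x, float)
    if np.all(x == 0):
        return 1.0, "all-zero group; signed-rank undefined"
    return float(stats.wilcoxon(x, alternative="two-sided").pvalue), ""


def group_tests(values_by_group: dict[str, np.ndarray]) -> GroupTestReport:
    """Group tests used for ΔSleep / ΔP(doze) / ΔP(wake) panels.

    Per group: two-sided Wilcoxon signed-rank p for H0 median = 0 (an
    all-zero group is flagged and reported as p = 1).  Per group pair:
    two-sided Wilcoxon rank-sum (Mann-Whitney) p.
    """
    for name, v in values_by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    signed, flags = {}, {}
    for name, v in values_by_group.items():
        p, flag = _signed_rank_zero(np.asarray(v, float))
        signed[name] = p
        if flag:
            flags[name] = flag
    names = list(values_by_group)
    pairs = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairs[(a, b)] = float(
                stats.mannwhitneyu(
                    values_by_group[a], values_by_group[b], alternative="two-sided"
                ).pvalue
            )
    return GroupTestReport(signed_rank=signed, rank_sum=pairs, flags=flags)


def activation_delta(
    illuminated: pd.Series | np.ndarray,
    dark_cohort: pd.Series | np.ndarray,
) -> np.ndarray:
    """ΔSleep for optogenetic activation: per illuminated fly, hour-2 sleep
    minus the mean hour-2 sleep of the never-illuminated cohort."""
    dark = np.asarray(dark_cohort, float)
    if dark.size == 0:
        raise ValueError("empty dark cohort")
    return np.asarray(illuminated, float) - dark.mean()
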