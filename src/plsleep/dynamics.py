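"""Sleep-depth dynamics: P(doze) and P(wake) per 30-min window.

P(doze) is the per-minute probability of an active minute being followed
by a non-active minute; P(wake) the reverse.  Both are conditional
transition probabilities — transitions divided by source minutes with an
observed successor — so they lie in [0, 1].  The successor of a window's
last minute is taken from the next window when data exist there (context
rule), so counts summed over windows equal counts on the undivided
series.

By default "active" means locomotion > 0 in the minute (``state_basis=
'activity'``); ``state_basis='sleep_state'`` instead uses the 5-min-rule
sleep/wake states, since both readings are compatible with the standard
description of these statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sleep import MINUTE_S, score_sleep

__all__ = ["transition_probs", "delta_transition"]


def _states(g: pd.DataFrame, state_basis: str) -> np.ndarray:
    if state_basis == "activity":
        return g["dist_mm"].to_numpy(float) > 0
    if state_basis == "sleep_state":
        if "asleep" not in g.columns:
            g = score_sleep(g)
        return ~g["asleep"].to_numpy(bool)  # "active" = awake
    raise ValueError(f"unknown state_basis {state_basis!r}")


def transition_probs(
    minutes: pd.DataFrame,
    window_min: int = 30,
    state_basis: str = "activity",
) -> pd.DataFrame:
    """Per-fly, per-window transition counts and probabilities.

    Parameters
    ----------
    minutes
        Per-minute series from :func:`plsleep.sleep.bin_minutes` (scored
        with :func:`~plsleep.sleep.score_sleep` when ``state_basis=
        'sleep_state'``), contiguous per fly.
    window_min
        Window width in minutes (windows anchored at t = 0).
    state_basis
        ``'activity'`` (locomotion > 0) or ``'sleep_state'`` (5-min rule).

    Returns
    -------
    DataFrame ``fly_id, window_start, n_active_src, n_inactive_src,
    n_doze, n_wake, p_doze, p_wake``; probabilities are NaN when a window
    has no source minutes of that kind.
    """
    win_s = window_min * MINUTE_S
    out = []
    for fly_id, g in minutes.groupby("fly_id", sort=False, observed=True):
        g = g.sort_values("minute_start")
        ms = g["minute_start"].to_numpy(float)
        if len(ms) > 1 and not np.allclose(np.diff(ms), MINUTE_S):
            raise ValueError(f"gap in minute grid for fly {fly_id!r}")
        active = _states(g, state_basis)
        valid = g["valid"].to_numpy(bool) if "valid" in g.columns else np.ones(len(g), bool)
        # source minutes: all but the last, and both ends of the transition observed
        src_ok = valid[:-1] & valid[1:]
        src_active = active[:-1]
        doze = src_ok & src_active & ~active[1:]
        wake = src_ok & ~src_active & active[1:]
        win = np.floor(ms[:-1] / win_s) * win_s
        rec = pd.DataFrame(
            {
                "window_start": win,
                "a_src": src_ok & src_active,
                "i_src": src_ok & ~src_active,
                "doze": doze,
                "wake": wake,
            }
        )
        agg = rec.groupby("window_start", sort=True).sum().reset_index()
        agg.insert(0, "fly_id", fly_id)
        agg = agg.rename(
            columns={
                "a_src": "n_active_src",
                "i_src": "n_inactive_src",
                "doze": "n_doze",
                "wake": "n_wake",
            }
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            agg["p_doze"] = np.where(
                agg["n_active_src"] > 0, agg["n_doze"] / agg["n_active_src"], np.nan
            )
            agg["p_wake"] = np.where(
                agg["n_inactive_src"] > 0, agg["n_wake"] / agg["n_inactive_src"], np.nan
            )
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def delta_transition(exp: pd.DataFrame, ctrl: pd.DataFrame) -> pd.DataFrame:
    """Per-fly ΔP(doze)/ΔP(wake): fly value minus control-cohort mean.

    Windows where either side is missing (NaN probability or no control
    fly with a defined value) are skipped; an error is raised when no
    window overlaps at all.
    """
    ctrl_mean = ctrl.groupby("window_start")[["p_doze", "p_wake"]].mean()
    out = exp.merge(
        ctrl_mean.rename(columns={"p_doze": "ctrl_doze", "p_wake": "ctrl_wake"}),
        on="window_start",
        how="inner",
    )
    out["dp_doze"] = out["p_doze"] - out["ctrl_doze"]
    out["dp_wake"] = out["p_wake"] - out["ctrl_wake"]
    out = out[["fly_id", "window_start", "dp_doze", "dp_wake"]]
    if out[["dp_doze", "dp_wake"]].isna().all().all() or len(out) == 0:
        raise ValueError("no overlapping defined windows between cohorts")
    return out
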