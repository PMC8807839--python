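"""Synthetic-data generators with known ground truth.

Every raw input the analysis stages consume can be simulated here:

* locomotion — a two-state (active/inactive) Markov chain over minutes,
  with optional time-windowed transition-probability changes (e.g. sleep
  deepening confined to the 1-3 h post-training window); active minutes
  emit 5 Hz frame displacements whose per-minute totals follow a
  log-normal law with median well above the 3.6 mm activity threshold;
* courtship indices — Beta draws scaled to [0, 100] parameterized by a
  target median and a concentration;
* luminescence plates — AR(1) background plus a condition-dependent
  Gaussian bump in time, with empty wells carrying background only;
* calcium traces — baseline fluorescence plus a pulse-locked
  rise/decay response kernel and Gaussian noise;
* connectome tables — planted type-level edges with Poisson pair weights
  over a background of sparse weak edges.

All generators are deterministic given a seed (or an explicit Generator)
and return ground truth alongside the data so recovery is testable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calcium import StimProtocol

__all__ = [
    "sim_minute_states",
    "sim_locomotion",
    "sim_training_cohorts",
    "sim_courtship",
    "sim_luminescence",
    "pulse_response",
    "sim_calcium",
    "sim_connectome",
]

MINUTE_S = 60.0


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------- locomotion

def sim_minute_states(
    n_flies: int,
    n_min: int,
    p_doze: float = 0.1,
    p_wake: float = 0.3,
    effects: list[tuple[float, float, float, float]] | None = None,
    t_start_s: float = 0.0,
    initial: str = "stationary",
    rng=None,
) -> np.ndarray:
    """Simulate per-minute active/inactive states, shape (n_flies, n_min).

    ``p_doze`` is P(active -> inactive) per minute and ``p_wake``
    P(inactive -> active).  ``effects`` is a list of
    ``(start_s, end_s, p_doze, p_wake)`` overrides applied to minutes
    whose start falls in ``[start_s, end_s)``.  ``initial`` is
    ``'stationary'`` (draw from the baseline stationary law),
    ``'active'`` or ``'inactive'``.
    """
    for p in (p_doze, p_wake):
        if not 0 <= p <= 1:
            raise ValueError("transition probabilities must lie in [0, 1]")
    rng = _rng(rng)
    minute_start = t_start_s + MINUTE_S * np.arange(n_min)
    pd_t = np.full(n_min, p_doze)
    pw_t = np.full(n_min, p_wake)
    for start, end, pdz, pwk in effects or []:
        if not (0 <= pdz <= 1 and 0 <= pwk <= 1):
            raise ValueError("effect-window probabilities must lie in [0, 1]")
        m = (minute_start >= start) & (minute_start < end)
        pd_t[m], pw_t[m] = pdz, pwk

    active = np.empty((n_flies, n_min), dtype=bool)
    if initial == "active":
        active[:, 0] = True
    elif initial == "inactive":
        active[:, 0] = False
    elif initial == "stationary":
        total = p_doze + p_wake
        p_inactive = p_doze / total if total > 0 else 0.0
        active[:, 0] = rng.random(n_flies) >= p_inactive
    else:
        raise ValueError(f"unknown initial state {initial!r}")
    u = rng.random((n_flies, n_min - 1)) if n_min > 1 else None
    for j in range(1, n_min):
        prev = active[:, j - 1]
        # transition governed by the probabilities in force at the new minute
        stay_active = u[:, j - 1] >= pd_t[j]
        wake_up = u[:, j - 1] < pw_t[j]
        active[:, j] = np.where(prev, stay_active, wake_up)
    return active


def sim_locomotion(
    n_flies: int,
    duration_min: int = 720,
    p_doze: float = 0.1,
    p_wake: float = 0.3,
    effects: list[tuple[float, float, float, float]] | None = None,
    sample_rate: float = 5.0,
    t_start_s: float = 0.0,
    dist_median_mm: float = 6.0,
    dist_sigma: float = 0.2,
    condition: str = "sim",
    fly_prefix: str = "fly",
    initial: str = "stationary",
    rng=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate frame-level locomotion traces for a cohort.

    Minute states come from :func:`sim_minute_states`; each active minute
    draws a total displacement from a log-normal law (median
    ``dist_median_mm``, log-SD ``dist_sigma``) spread uniformly over its
    frames; inactive minutes emit zero displacement.

    Returns ``(trace, truth)``: ``trace`` is the long-format frame table
    (``fly_id, condition, t_s, d_mm``) the scoring pipeline reads and
    ``truth`` the generating per-minute state table
    (``fly_id, minute_start, active``).
    """
    rng = _rng(rng)
    active = sim_minute_states(
        n_flies, duration_min, p_doze, p_wake, effects, t_start_s, initial, rng
    )
    fpm = int(round(sample_rate * MINUTE_S))
    dist = np.where(
        active,
        np.exp(np.log(dist_median_mm) + dist_sigma * rng.standard_normal(active.shape)),
        0.0,
    )
    fly_ids = [f"{fly_prefix}{i:03d}" for i in range(n_flies)]
    n_frames = duration_min * fpm
    t = t_start_s + np.arange(n_frames) / sample_rate
    d = np.repeat(dist, fpm, axis=1) / fpm  # equal split across frames
    # categorical ids keep multi-million-row cohort frames cheap
    fly_col = pd.Categorical.from_codes(
        np.repeat(np.arange(n_flies), n_frames), categories=fly_ids
    )
    trace = pd.DataFrame(
        {
            "fly_id": fly_col,
            "condition": condition,
            "t_s": np.tile(t, n_flies),
            "d_mm": d.ravel(),
        }
    )
    minute_start = t_start_s + MINUTE_S * np.arange(duration_min)
    truth = pd.DataFrame(
        {
            "fly_id": pd.Categorical.from_codes(
                np.repeat(np.arange(n_flies), duration_min), categories=fly_ids
            ),
            "minute_start": np.tile(minute_start, n_flies),
            "active": active.ravel(),
        }
    )
    return trace, truth


def sim_training_cohorts(
    seed=None,
    n_flies: int = 45,
    durations_h: tuple = (0, 1, 2, 4, 6),
    session_min: int = 180,
    deepened_h: tuple = (4, 6),
    p_doze: float = 0.1,
    p_wake: float = 0.3,
    deep_p_doze: float = 0.3,
    deep_p_wake: float = 0.1,
    tp_window_s: tuple[float, float] = (3600.0, 10800.0),
    sample_rate: float = 5.0,
) -> dict:
    """Simulate the post-training sleep experiment: one cohort per
    training duration, with sleep deepening planted only in the 1-3 h
    post-training window of the ``deepened_h`` cohorts.  The 0-h cohort
    is the naive control.  Returns {duration_h: (trace, truth)}.
    """
    rng = _rng(seed)
    out = {}
    for dur in durations_h:
        effects = (
            [(tp_window_s[0], tp_window_s[1], deep_p_doze, deep_p_wake)]
            if dur in deepened_h
            else None
        )
        out[dur] = sim_locomotion(
            n_flies,
            duration_min=session_min,
            p_doze=p_doze,
            p_wake=p_wake,
            effects=effects,
            sample_rate=sample_rate,
            condition=f"{dur}h",
            fly_prefix=f"t{dur}h_fly",
            rng=rng,
        )
    return out


# ----------------------------------------------------------------- courtship

def _beta_from_median(median_ci: float, concentration: float) -> tuple[float, float]:
    """Beta(a, b) with a + b = concentration whose median ~ median_ci/100.

    Uses the standard median approximation (a - 1/3)/(a + b - 2/3)."""
    m = median_ci / 100.0
    if not 0 < m < 1:
        raise ValueError("target median CI must lie in (0, 100)")
    a = m * (concentration - 2.0 / 3.0) + 1.0 / 3.0
    b = concentration - a
    if a <= 0 or b <= 0:
        raise ValueError("concentration too small for the requested median")
    return a, b


def sim_courtship(
    n_trained: int,
    n_naive: int,
    median_trained: float = 30.0,
    median_naive: float = 80.0,
    concentration: float = 6.0,
    arm: str = "experimental",
    rng=None,
) -> pd.DataFrame:
    """Simulate courtship-index records for one arm.

    CIs are Beta draws scaled to [0, 100] with group medians converging
    to the configured targets; the trained-vs-naive median shift encodes
    memory.  Returns ``fly_id, arm, condition, ci``.
    """
    rng = _rng(rng)
    at, bt = _beta_from_median(median_trained, concentration)
    an, bn = _beta_from_median(median_naive, concentration)
    ci = np.concatenate(
        [100 * rng.beta(at, bt, n_trained), 100 * rng.beta(an, bn, n_naive)]
    )
    return pd.DataFrame(
        {
            "fly_id": [f"{arm}_{i:03d}" for i in range(n_trained + n_naive)],
            "arm": arm,
            "condition": ["trained"] * n_trained + ["naive"] * n_naive,
            "ci": ci,
        }
    )


# -------------------------------------------------------------- luminescence

def bump_amplitude(training_h: float, mode: str, amp: float) -> float:
    """Post-training bump amplitude as a function of training duration.

    ``linear``  — grows linearly with duration (amp is the per-hour gain);
    ``peaked``  — Gaussian peak at 2 h training (SD 1 h);
    ``step``    — zero below 4 h, ``amp`` at 4 h and above.
    """
    if mode == "linear":
        return amp * training_h
    if mode == "peaked":
        return amp * float(np.exp(-((training_h - 2.0) ** 2) / 2.0))
    if mode == "step":
        return amp if training_h >= 4 else 0.0
    raise ValueError(f"unknown amplitude mode {mode!r}")


def sim_luminescence(
    n_wells: int = 20,
    n_empty: int = 3,
    training_h: float = 6.0,
    mode: str = "step",
    amp: float = 50.0,
    base_lum: float = 100.0,
    bg_lum: float = 20.0,
    bump_center_min: float = 120.0,
    bump_sd_min: float = 45.0,
    noise_sd: float = 10.0,
    ar_phi: float = 0.5,
    session_min: float = 600.0,
    dt_min: float = 15.0,
    rng=None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one luminescence plate: empty, naive and experienced wells.

    Wells are sampled every ``dt_min`` minutes from t = 0 (end of
    training) for ``session_min``.  Empty wells carry AR(1) background
    noise around ``bg_lum``; fly wells add a constant reporter level
    ``base_lum`` and, for the experienced group, a Gaussian-in-time bump
    centered ``bump_center_min`` after training whose amplitude follows
    :func:`bump_amplitude`.  Naive wells (training 0 h) never get a bump.

    Returns ``(plate, truth)`` with ``plate`` long-format
    ``well_id, role, training_h, t_min, lum`` and ``truth`` the planted
    amplitude and noise parameters.
    """
    rng = _rng(rng)
    t = np.arange(0.0, session_min + dt_min / 2, dt_min)
    amp_exp = bump_amplitude(training_h, mode, amp)
    bump = np.exp(-((t - bump_center_min) ** 2) / (2 * bump_sd_min**2))

    def ar1(n_rows: int) -> np.ndarray:
        eps = noise_sd * np.sqrt(1 - ar_phi**2) * rng.standard_normal((n_rows, t.size))
        x = np.empty_like(eps)
        x[:, 0] = noise_sd * rng.standard_normal(n_rows)
        for j in range(1, t.size):
            x[:, j] = ar_phi * x[:, j - 1] + eps[:, j]
        return x

    rows = []
    for role, n, signal in (
        ("empty", n_empty, None),
        ("naive", n_wells, base_lum),
        ("experienced", n_wells, base_lum + amp_exp * bump),
    ):
        lum = bg_lum + ar1(n)
        if signal is not None:
            lum = lum + signal
        for i in range(n):
            rows.append(
                pd.DataFrame(
                    {
                        "well_id": f"{role[:3]}{i:02d}",
                        "role": role,
                        "training_h": 0.0 if role != "experienced" else training_h,
                        "t_min": t,
                        "lum": lum[i],
                    }
                )
            )
    truth = {
        "amplitude": amp_exp,
        "mode": mode,
        "bump_center_min": bump_center_min,
        "bump_sd_min": bump_sd_min,
        "base_lum": base_lum,
        "bg_lum": bg_lum,
    }
    return pd.concat(rows, ignore_index=True), truth


# ------------------------------------------------------------------- calcium

def pulse_response(
    t,
    proto: StimProtocol = StimProtocol(),
    amplitude: float = 0.5,
    tau_rise: float = 1.0,
    tau_decay: float = 4.0,
) -> np.ndarray:
    """Deterministic pulse-locked ΔF/F response kernel, summed over pulses.

    During each pulse the response rises as ``A·(1 − exp(−Δt/τ_rise))``
    and after pulse offset decays exponentially with ``τ_decay``.  The
    amplitude (signed) scales the whole kernel linearly, so an inhibitory
    connection is simply a negative amplitude.
    """
    t = np.asarray(t, float)
    r = np.zeros_like(t)
    for onset in proto.onsets:
        dt_on = t - onset
        during = (dt_on >= 0) & (dt_on < proto.pulse_s)
        after = dt_on >= proto.pulse_s
        r[during] += amplitude * (1 - np.exp(-dt_on[during] / tau_rise))
        peak = amplitude * (1 - np.exp(-proto.pulse_s / tau_rise))
        r[after] += peak * np.exp(-(dt_on[after] - proto.pulse_s) / tau_decay)
    return r


def sim_calcium(
    n_flies: int = 7,
    proto: StimProtocol = StimProtocol(),
    amplitude: float = 0.5,
    tau_rise: float = 1.0,
    tau_decay: float = 4.0,
    noise_sd: float = 0.05,
    f_baseline: float = 100.0,
    volume_rate: float = 1.0,
    roi: str = "roi",
    rng=None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate ROI fluorescence traces for a functional-connectivity run.

    ``f(t) = f_baseline · (1 + response(t) + noise)`` with the response
    from :func:`pulse_response` (in ΔF/F units; sign gives the connection
    direction) and i.i.d. Gaussian noise of SD ``noise_sd`` (ΔF/F units).

    Returns ``(traces, truth)``; traces are long-format
    ``fly_id, roi, t_s, f``.
    """
    rng = _rng(rng)
    t = np.arange(0.0, proto.session_s, 1.0 / volume_rate)
    resp = pulse_response(t, proto, amplitude, tau_rise, tau_decay)
    rows = []
    for i in range(n_flies):
        f = f_baseline * (1.0 + resp + noise_sd * rng.standard_normal(t.size))
        rows.append(
            pd.DataFrame({"fly_id": f"fly{i:02d}", "roi": roi, "t_s": t, "f": f})
        )
    truth = {
        "amplitude": amplitude,
        "tau_rise": tau_rise,
        "tau_decay": tau_decay,
        "noise_sd": noise_sd,
        "f_baseline": f_baseline,
    }
    return pd.concat(rows, ignore_index=True), truth


# ---------------------------------------------------------------- connectome

def sim_connectome(
    types: tuple = ("MBON-g2a1", "MBON-b2mp", "SFS", "vFB", "dFB"),
    n_per_type: int = 5,
    planted: tuple = (("MBON-g2a1", "SFS"), ("MBON-b2mp", "SFS"), ("SFS", "vFB")),
    planted_mean: float = 20.0,
    noise_pair_prob: float = 0.3,
    noise_mean: float = 2.0,
    rng=None,
) -> tuple[pd.DataFrame, set]:
    """Simulate a directed synapse edge table with planted type edges.

    Neuron pairs inside planted (pre-type, post-type) edges draw Poisson
    weights with mean ``planted_mean``; every other ordered type pair
    contributes sparse noise pairs (probability ``noise_pair_prob`` per
    neuron pair) with Poisson mean ``noise_mean``.  Zero-weight draws are
    dropped.  Returns ``(table, planted_set)``.
    """
    rng = _rng(rng)
    neurons = {
        tp: [f"{tp}_{i}" for i in range(n_per_type)] for tp in types
    }
    planted_set = set(planted)
    rows = []
    for pre_t in types:
        for post_t in types:
            if pre_t == post_t:
                continue
            for pre in neurons[pre_t]:
                for post in neurons[post_t]:
                    if (pre_t, post_t) in planted_set:
                        w = rng.poisson(planted_mean)
                    elif rng.random() < noise_pair_prob:
                        w = rng.poisson(noise_mean)
                    else:
                        continue
                    if w > 0:
                        rows.append((pre, post, pre_t, post_t, int(w)))
    table = pd.DataFrame(
        rows, columns=["pre_id", "post_id", "pre_type", "post_type", "weight"]
    )
    return table, planted_set
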