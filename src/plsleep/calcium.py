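"""Calcium-imaging analysis and functional-connectivity calls.

ΔF/F = (f(t) - F0)/F0 with F0 the mean fluorescence of the first 10 s of
the session (before the first optogenetic pulse).  The stimulation
protocol is six 5-s pulses with a 10-s latency to the first pulse and
30-s intervals between pulse onsets (200-s session); per-pulse ΔF/F
segments are aligned to pulse onset and averaged.  A functional
connection is called when the per-fly mean ΔF/F during stimulation
differs from the per-fly pre-stimulation baseline at p < 0.05
(two-sided); the sign of the mean effect gives the direction
(excitatory / inhibitory).  Spontaneous activity is simply the mean raw
fluorescence over a 60-s recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StimProtocol",
    "dff",
    "epoch_average",
    "baseline_stim_means",
    "connectivity_call",
    "spontaneous_activity",
    "ConnectivityCall",
]


@dataclass(frozen=True)
class StimProtocol:
    """Optogenetic pulse-train protocol (defaults: the 6 x 5 s train)."""

    n_pulses: int = 6
    pulse_s: float = 5.0
    first_onset_s: float = 10.0
    onset_interval_s: float = 30.0
    session_s: float = 200.0

    def __post_init__(self):
        last_off = self.first_onset_s + (self.n_pulses - 1) * self.onset_interval_s + self.pulse_s
        if last_off > self.session_s:
            raise ValueError("pulse train does not fit inside the session")

    @property
    def onsets(self) -> np.ndarray:
        return self.first_onset_s + self.onset_interval_s * np.arange(self.n_pulses)

    def stim_mask(self, t: np.ndarray) -> np.ndarray:
        """True where t falls inside any pulse interval [onset, onset+pulse_s)."""
        t = np.asarray(t, float)
        rel = t[:, None] - self.onsets[None, :]
        return ((rel >= 0) & (rel < self.pulse_s)).any(axis=1)


def dff(t, f, baseline_s: float = 10.0) -> tuple[np.ndarray, float]:
    """ΔF/F trace and its baseline F0 (mean f over t in [0, baseline_s))."""
    t = np.asarray(t, float)
    f = np.asarray(f, float)
    base = f[(t >= 0) & (t < baseline_s)]
    if base.size < 2:
        raise ValueError("fewer than 2 samples in the baseline window")
    f0 = float(base.mean())
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0} <= 0; ΔF/F undefined")
    return (f - f0) / f0, f0


def epoch_average(
    t,
    dff_trace,
    proto: StimProtocol = StimProtocol(),
    pre_s: float = 10.0,
    post_s: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pulse-onset-aligned mean ΔF/F response.

    Each pulse epoch is resampled (nearest sample) onto a common
    onset-relative grid spanning ``[-pre_s, post_s)`` at the native median
    sampling step, then averaged pointwise across the ``proto.n_pulses``
    epochs.  Returns ``(t_rel, mean_response)``.
    """
    t = np.asarray(t, float)
    y = np.asarray(dff_trace, float)
    if t.size < 2:
        raise ValueError("trace too short")
    dt = float(np.median(np.diff(t)))
    if (proto.onsets - pre_s < t[0] - dt / 2).any() or (
        proto.onsets + post_s > t[-1] + dt / 2
    ).any():
        raise ValueError("an epoch extends outside the recording")
    grid = np.arange(-pre_s, post_s, dt)
    segs = np.empty((proto.n_pulses, grid.size))
    for i, onset in enumerate(proto.onsets):
        idx = np.clip(np.searchsorted(t, onset + grid), 0, t.size - 1)
        left = np.clip(idx - 1, 0, t.size - 1)
        nearer_left = np.abs(t[left] - (onset + grid)) < np.abs(t[idx] - (onset + grid))
        segs[i] = y[np.where(nearer_left, left, idx)]
    return grid, segs.mean(axis=0)


def baseline_stim_means(
    t, dff_trace, proto: StimProtocol = StimProtocol(), baseline_s: float = 10.0
) -> tuple[float, float]:
    """Per-fly (baseline, stimulated) mean ΔF/F.

    Baseline = mean over the pre-first-pulse window [0, baseline_s);
    stimulated = mean over the union of the pulse intervals.
    """
    t = np.asarray(t, float)
    y = np.asarray(dff_trace, float)
    base = y[(t >= 0) & (t < baseline_s)]
    stim = y[proto.stim_mask(t)]
    if base.size == 0 or stim.size == 0:
        raise ValueError("baseline or stimulation window not covered by the trace")
    return float(base.mean()), float(stim.mean())


@dataclass
class ConnectivityCall:
    direction: str  # excitatory | inhibitory | none
    p: float
    effect: float  # mean stimulated-minus-baseline ΔF/F
    n_flies: int
    test: str = field(default="t")


def connectivity_call(
    baseline_means,
    stim_means,
    alpha: float = 0.05,
    test: str = "auto",
    paired: bool = True,
) -> ConnectivityCall:
    """Classify a connection from per-fly baseline and stimulated ΔF/F.

    Two-sided comparison across flies (paired within fly by default;
    ``paired=False`` gives the unpaired variants).  ``test`` is ``'t'``,
    ``'wilcoxon'`` (rank-based) or ``'auto'`` — a Shapiro normality check
    at 0.05 picks between them.  Direction is excitatory when p < alpha
    with positive mean effect, inhibitory when negative, else none.
    """
    base = np.asarray(baseline_means, float)
    stim = np.asarray(stim_means, float)
    if base.size != stim.size and paired:
        raise ValueError("paired comparison needs equal-length groups")
    n = stim.size
    if n < 3 or base.size < 3:
        raise ValueError("need >= 3 flies for a connectivity call")
    effect = float(stim.mean() - base.mean())
    diffs = stim - base if paired else None

    chosen = test
    if test == "auto":
        sample = diffs if paired else np.concatenate([base, stim])
        if np.ptp(sample) == 0:
            chosen = "wilcoxon"
        else:
            chosen = "t" if stats.shapiro(sample).pvalue >= 0.05 else "wilcoxon"
    if chosen == "t":
        res = stats.ttest_rel(stim, base) if paired else stats.ttest_ind(stim, base)
    elif chosen == "wilcoxon":
        if paired:
            if np.all(diffs == 0):
                return ConnectivityCall("none", 1.0, effect, n, "wilcoxon")
            res = stats.wilcoxon(diffs, alternative="two-sided")
        else:
            res = stats.mannwhitneyu(stim, base, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(res.pvalue)
    if p < alpha:
        direction = "excitatory" if effect > 0 else "inhibitory"
    else:
        direction = "none"
    return ConnectivityCall(direction, p, effect, n, chosen)


def spontaneous_activity(t, f, span_s: float = 60.0) -> float:
    """Mean raw fluorescence over the first ``span_s`` seconds."""
    t = np.asarray(t, float)
    f = np.asarray(f, float)
    sel = f[(t >= 0) & (t < span_s)]
    if sel.size == 0:
        raise ValueError("recording does not cover the requested span")
    return float(sel.mean())
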