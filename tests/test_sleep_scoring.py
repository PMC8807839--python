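"""Sleep scoring: minute binning, the 5-min rule, pooling and ΔSleep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plsleep import sleep
from plsleep.sleep import (
    activation_delta,
    bin_minutes,
    delta_sleep,
    group_tests,
    pool_sleep,
    score_sleep,
    window_mean,
)

from conftest import frames_from_minute_dists, minutes_from_pattern


def brute_force_sleep(active: np.ndarray, min_run: int = 5) -> np.ndarray:
    """Independent run-length scanner: asleep iff inside a run of
    >= min_run consecutive inactive minutes."""
    n = len(active)
    asleep = np.zeros(n, bool)
    i = 0
    while i < n:
        if not active[i]:
            j = i
            while j < n and not active[j]:
                j += 1
            if j - i >= min_run:
                asleep[i:j] = True
            i = j
        else:
            i += 1
    return asleep


class TestBinMinutes:
    def test_threshold_boundary_is_active(self):
        m = bin_minutes(frames_from_minute_dists([3.6, 3.5999, 0.0]))
        assert m["active"].tolist() == [True, False, False]
        assert m.loc[2, "dist_mm"] == 0.0

    def test_sustained_locomotion_all_active(self):
        # 0.02 mm per 5 Hz frame = 6 mm/min, well above 3.6
        t = np.arange(10 * 300) / 5.0
        tr = pd.DataFrame({"fly_id": "f", "t_s": t, "d_mm": 0.02})
        m = bin_minutes(tr)
        assert len(m) == 10
        assert m["active"].all()
        np.testing.assert_allclose(m["dist_mm"], 6.0)

    def test_minute_sums_match_brute_force(self, rng):
        t = np.arange(7 * 300) / 5.0
        d = rng.exponential(0.01, t.size)
        m = bin_minutes(pd.DataFrame({"fly_id": "f", "t_s": t, "d_mm": d}))
        expected = [d[(t >= 60 * k) & (t < 60 * (k + 1))].sum() for k in range(7)]
        np.testing.assert_allclose(m["dist_mm"], expected)

    def test_incomplete_trailing_bin_dropped(self):
        t = np.arange(450) / 5.0  # 1.5 minutes
        m = bin_minutes(pd.DataFrame({"fly_id": "f", "t_s": t, "d_mm": 0.0}))
        assert len(m) == 1

    def test_sparse_minute_flagged_invalid(self):
        tr = frames_from_minute_dists([6.0, 6.0])
        tr = pd.concat(
            [tr, pd.DataFrame({"fly_id": "f0", "t_s": [120.0, 179.8], "d_mm": [0.0, 0.0]})],
            ignore_index=True,
        )
        m = bin_minutes(tr)
        assert m["valid"].tolist() == [True, True, False]

    def test_errors(self):
        with pytest.raises(ValueError):
            bin_minutes(pd.DataFrame(columns=["fly_id", "t_s", "d_mm"]))
        bad = pd.DataFrame({"fly_id": "f", "t_s": [0.0, 0.2, 0.1] + list(np.arange(3, 70, 0.2)), "d_mm": 0.0})
        with pytest.raises(ValueError, match="non-monotone"):
            bin_minutes(bad)


class TestScoreSleep:
    @pytest.mark.parametrize(
        "pattern,n_sleep",
        [
            ("IIIII", 5),  # run of exactly 5 counts
            ("AIIIIA", 0),  # 4-run flanked by active minutes
            ("A IIIII A IIII A", 5),
            ("IIIIIIII", 8),  # boundary-truncated run long enough
            ("AAAA", 0),
        ],
    )
    def test_run_rule(self, pattern, n_sleep):
        scored = score_sleep(minutes_from_pattern(pattern))
        assert scored["asleep"].sum() == n_sleep

    def test_invalid_minutes_break_runs(self):
        # 9 immobile minutes with an invalid one in the middle: neither
        # side reaches 5, so no sleep is fabricated
        scored = score_sleep(minutes_from_pattern("IIIIXIIII"))
        assert scored["asleep"].sum() == 0

    def test_gap_in_grid_is_error(self):
        m = minutes_from_pattern("IIIIII")
        m = m[m["minute_start"] != 120.0]
        with pytest.raises(ValueError, match="gap"):
            score_sleep(m)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=80))
    def test_matches_brute_force_scanner(self, states):
        active = np.array(states)
        pattern = "".join("A" if a else "I" for a in active)
        scored = score_sleep(minutes_from_pattern(pattern))
        np.testing.assert_array_equal(
            scored["asleep"].to_numpy(), brute_force_sleep(active)
        )

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=80))
    def test_asleep_implies_inactive(self, states):
        pattern = "".join("A" if a else "I" for a in states)
        scored = score_sleep(minutes_from_pattern(pattern))
        assert not (scored["asleep"] & scored["active"]).any()


class TestThresholdMonotonicity:
    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=5, max_size=30))
    def test_raising_threshold_never_decreases_sleep(self, dists):
        tr = frames_from_minute_dists(dists)
        lo = score_sleep(bin_minutes(tr, threshold_mm=2.0))
        hi = score_sleep(bin_minutes(tr, threshold_mm=5.0))
        # inactive set grows with the threshold ...
        assert (~lo["active"] <= ~hi["active"]).all()
        # ... hence total sleep cannot drop
        assert hi["asleep"].sum() >= lo["asleep"].sum()


class TestPoolSleep:
    def test_saturated_and_empty_bins(self):
        scored = score_sleep(minutes_from_pattern("I" * 30 + "A" * 30))
        pooled = pool_sleep(scored)
        assert pooled["sleep_min"].tolist() == [30.0, 0.0]

    def test_bout_straddling_bin_boundary(self):
        # 12-min bout starting at minute 25: 5 min in the first 30-min
        # bin, 7 in the second
        pattern = "A" * 25 + "I" * 12 + "A" * 23
        pooled = pool_sleep(score_sleep(minutes_from_pattern(pattern)))
        assert pooled["sleep_min"].tolist() == [5.0, 7.0]

    def test_conservation(self, rng):
        pattern = "".join(rng.choice(["A", "I"], 240))
        scored = score_sleep(minutes_from_pattern(pattern))
        pooled = pool_sleep(scored)
        assert pooled["sleep_min"].sum() == scored["asleep"].sum()


class TestDeltaSleep:
    def _binned(self, values_by_fly):
        rows = []
        for fid, vals in values_by_fly.items():
            for b, v in enumerate(vals):
                rows.append({"fly_id": fid, "bin_start": 1800.0 * b, "sleep_min": float(v)})
        return pd.DataFrame(rows)

    def test_arithmetic(self):
        exp = self._binned({"e0": [25, 25]})
        ctrl = self._binned({"c0": [10, 10]})
        d = delta_sleep(exp, ctrl)
        assert d["delta_min"].tolist() == [15.0, 15.0]

    def test_self_contrast_averages_to_zero(self, rng):
        cohort = self._binned({f"f{i}": rng.integers(0, 31, 4) for i in range(6)})
        d = delta_sleep(cohort, cohort)
        means = d.groupby("bin_start")["delta_min"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-12)

    def test_misaligned_grids_error(self):
        exp = self._binned({"e0": [5]})
        ctrl = self._binned({"c0": [5]})
        ctrl["bin_start"] += 900.0
        with pytest.raises(ValueError, match="overlap"):
            delta_sleep(exp, ctrl)


class TestWindowMean:
    def test_tp13_selects_four_bins_and_averages(self):
        rows = [
            {"fly_id": "f", "bin_start": 60.0 * m, "delta_min": v}
            for m, v in [(0, 99), (30, 99), (60, 2), (90, 4), (120, 6), (150, 8), (180, 99)]
        ]
        res = window_mean(pd.DataFrame(rows), sleep.TP13_S)
        assert res["f"] == 5.0

    def test_empty_window_errors(self):
        df = pd.DataFrame([{"fly_id": "f", "bin_start": 0.0, "delta_min": 1.0}])
        with pytest.raises(ValueError):
            window_mean(df, (3600.0, 10800.0))


class TestGroupTests:
    def test_constant_positive_group_exact_signed_rank(self):
        rep = group_tests({"g": np.full(10, 5.0)})
        assert rep.signed_rank["g"] == pytest.approx(2 * 2.0**-10, rel=1e-12)

    def test_all_zero_group_flagged(self):
        rep = group_tests({"z": np.zeros(8), "g": np.full(8, 2.0)})
        assert rep.signed_rank["z"] == 1.0
        assert "z" in rep.flags

    def test_identical_groups_rank_sum_p_one(self):
        x = np.arange(10.0)
        rep = group_tests({"a": x, "b": x.copy()})
        assert rep.rank_sum[("a", "b")] == pytest.approx(1.0)

    def test_null_calibration_uniform_p(self, rng):
        # symmetric noise around 0: p should be roughly uniform
        ps = []
        for _ in range(300):
            rep = group_tests({"g": rng.standard_normal(50)})
            ps.append(rep.signed_rank["g"])
        ps = np.asarray(ps)
        assert 0.02 < np.mean(ps < 0.05) < 0.10
        assert abs(np.mean(ps) - 0.5) < 0.06


class TestActivationDelta:
    def test_arithmetic_and_identity(self):
        d = activation_delta([35.0, 20.0], [10.0, 30.0])  # dark mean 20
        np.testing.assert_allclose(d, [15.0, 0.0])

    def test_empty_dark_cohort_errors(self):
        with pytest.raises(ValueError):
            activation_delta([10.0], [])

    def test_planted_sleep_promotion_positive(self, rng):
        from plsleep.simulate import sim_minute_states

        # illuminated cohort dozes more in its second hour
        dark = sim_minute_states(30, 120, 0.1, 0.3, rng=rng)
        lit = sim_minute_states(
            30, 120, 0.1, 0.3, effects=[(3600.0, 7200.0, 0.4, 0.05)], rng=rng
        )
        # hour-2 sleep proxy: inactive minutes in minutes 60..119
        dark_sleep = (~dark[:, 60:]).sum(axis=1)
        lit_sleep = (~lit[:, 60:]).sum(axis=1)
        assert activation_delta(lit_sleep, dark_sleep).mean() > 5
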