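"""Courtship-memory statistics: suppression index and permutation tests.

Long-term courtship memory is quantified from courtship indices (CI, the
percentage of a 10-min test spent courting) as the suppression index

    SI = 100 * (1 - median(CI+) / median(CI-))

where CI+ are trained and CI- naive males.  Significance comes from label
permutation: for H0 "SI = 0" the trained and naive CIs are pooled and
randomly re-assorted into simulated groups of the original sizes (default
100,000 permutations); for H0 "SI_exp = SI_ctrl" the experimental/control
arm labels are shuffled independently within the trained pool and within
the naive pool, preserving the trained/naive structure that is not under
test.  P-values are two-sided on |statistic| with the add-one correction,
so p is never exactly 0 and the test is valid at its nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["suppression_index", "perm_test_si_zero", "perm_test_si_equal", "SIResult"]

#: |SI| cap used when a permuted naive group has median 0 (the observed-data
#: case raises instead).  Keeps every permutation usable and n_perm fixed.
SI_SENTINEL = 100.0


def suppression_index(trained_ci, naive_ci) -> float:
    """SI = 100 * (1 - median(trained) / median(naive)), in percent."""
    trained = np.asarray(trained_ci, float)
    naive = np.asarray(naive_ci, float)
    if trained.size == 0 or naive.size == 0:
        raise ValueError("CI vectors must be nonempty")
    mn = np.median(naive)
    if mn <= 0:
        raise ValueError("median naive CI is 0; SI undefined")
    return float(100.0 * (1.0 - np.median(trained) / mn))


@dataclass
class SIResult:
    si_obs: float
    p: float
    n_perm: int
    seed: int | None
    null_type: str


def _si_capped(med_trained: np.ndarray, med_naive: np.ndarray) -> np.ndarray:
    """Vectorized SI with the sentinel convention for zero naive medians."""
    si = np.empty_like(med_trained, dtype=float)
    ok = med_naive > 0
    si[ok] = 100.0 * (1.0 - med_trained[ok] / med_naive[ok])
    bad = ~ok
    # naive median 0: full suppression impossible to exceed; trained median
    # > 0 means trained courts MORE than naive -> maximal negative SI
    si[bad] = np.where(med_trained[bad] > 0, -SI_SENTINEL, 0.0)
    return np.clip(si, -SI_SENTINEL, None)


def _perm_medians(
    pool: np.ndarray, n_first: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Median of the first-n and rest groups under random re-assortment.

    The pool is sorted first so that p depends only on the multiset of
    values, not on input order (exchangeability contract).
    """
    pool = np.sort(pool)
    idx = rng.random((n_perm, pool.size)).argsort(axis=1)
    perm = pool[idx]
    return np.median(perm[:, :n_first], axis=1), np.median(perm[:, n_first:], axis=1)


def perm_test_si_zero(
    trained_ci,
    naive_ci,
    n_perm: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SIResult:
    """Permutation test of H0: SI = 0.

    Trained and naive CIs are pooled and randomly re-assorted into
    simulated trained/naive groups of the original sizes; an SI is
    computed for each of ``n_perm`` permuted datasets and

        p = (1 + #{|SI_perm| >= |SI_obs|}) / (n_perm + 1).

    Deterministic given ``seed``.
    """
    trained = np.asarray(trained_ci, float)
    naive = np.asarray(naive_ci, float)
    if trained.size < 2 or naive.size < 2:
        raise ValueError("each group needs >= 2 observations")
    si_obs = suppression_index(trained, naive)
    pool = np.concatenate([trained, naive])
    if np.ptp(pool) == 0:
        return SIResult(si_obs, 1.0, n_perm, seed, "si_zero")
    if rng is None:
        rng = np.random.default_rng(seed)
    med_t, med_n = _perm_medians(pool, trained.size, n_perm, rng)
    si_perm = _si_capped(med_t, med_n)
    p = (1 + int(np.sum(np.abs(si_perm) >= abs(si_obs)))) / (n_perm + 1)
    return SIResult(si_obs, float(p), n_perm, seed, "si_zero")


def perm_test_si_equal(
    exp_trained,
    exp_naive,
    ctrl_trained,
    ctrl_naive,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> SIResult:
    """Permutation test of H0: SI_exp = SI_ctrl.

    The statistic is SI_exp - SI_ctrl.  The null is built by shuffling
    the experimental/control arm labels independently within the trained
    pool and within the naive pool, preserving group sizes; two-sided p
    with the add-one correction.  ``si_obs`` on the result holds the
    observed difference.
    """
    et, en = np.asarray(exp_trained, float), np.asarray(exp_naive, float)
    ct, cn = np.asarray(ctrl_trained, float), np.asarray(ctrl_naive, float)
    for name, v in (("exp_trained", et), ("exp_naive", en),
                    ("ctrl_trained", ct), ("ctrl_naive", cn)):
        if v.size == 0:
            raise ValueError(f"{name} is empty")
    stat_obs = suppression_index(et, en) - suppression_index(ct, cn)
    pool_t = np.concatenate([et, ct])
    pool_n = np.concatenate([en, cn])
    if np.ptp(pool_t) == 0 and np.ptp(pool_n) == 0:
        return SIResult(stat_obs, 1.0, n_perm, seed, "si_equal")
    rng = np.random.default_rng(seed)
    # independent within-condition shuffles; first block = experimental arm
    et_m, ct_m = _perm_medians(pool_t, et.size, n_perm, rng)
    en_m, cn_m = _perm_medians(pool_n, en.size, n_perm, rng)
    stat_perm = _si_capped(et_m, en_m) - _si_capped(ct_m, cn_m)
    p = (1 + int(np.sum(np.abs(stat_perm) >= abs(stat_obs)))) / (n_perm + 1)
    return SIResult(float(stat_obs), float(p), n_perm, seed, "si_equal")
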