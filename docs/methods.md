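# Methods notes

This note records the models behind each analysis stage, the defaults and
conventions chosen where the standard workflow leaves them open, what the
synthetic-data generators do and do not emulate, and known limitations.

## Sleep scoring

Locomotion arrives as per-frame body-center displacement (mm) at a nominal
5 Hz, on a time axis in seconds relative to the end of training (t = 0;
training time is negative). The chain is:

1. **Minute binning.** Minutes are half-open intervals [60k, 60k + 60)
   anchored at t = 0. A minute is *active* iff its summed displacement is
   **≥ 3.6 mm**. The boundary is assigned to *active* deliberately: "no
   locomotion" should mean strictly sub-threshold movement. The threshold
   and the comparison direction are configurable (`threshold_mm`), since
   tracker implementations differ on the boundary case.
2. **Completeness.** A minute with fewer than 50% of its expected frames
   is flagged invalid. Invalid minutes break sleep runs rather than extend
   them — the scorer never fabricates sleep across unobserved gaps. An
   incomplete trailing bin is dropped outright.
3. **Sleep rule.** A minute is asleep iff it lies in a maximal run of
   ≥ 5 consecutive inactive minutes. Runs truncated by the recording edge
   count only if the *observed* run already reaches 5 min; unobserved
   inactivity is never assumed.
4. **Pooling.** Sleep amount is counted per 30-min bin (half-open,
   anchored at t = 0); bins containing invalid or missing minutes are
   flagged.
5. **ΔSleep.** Per experimental fly and bin, sleep minus the control
   cohort's mean at that bin; defined only where the control mean exists.
6. **TP1-3.** The post-training analysis window is [1 h, 3 h). A 30-min
   bin belongs to a window iff its *start* lies inside it, so TP1-3 holds
   the bins starting at 60, 90, 120, 150 min. The half-open convention is
   used everywhere to avoid double counting.

Group statistics are two-sided Wilcoxon signed-rank (single group vs 0;
an all-zero group is flagged and reported as p = 1 since the statistic is
undefined there) and two-sided Wilcoxon rank-sum / Mann-Whitney between
groups, via scipy.

## Sleep-depth dynamics

P(doze) and P(wake) are conditional per-minute transition probabilities:
transitions divided by source minutes *with an observed successor*. This
normalization keeps both in [0, 1] and makes counts additive: summed over
windows they equal the counts of the undivided series, because a window's
last minute takes its successor from the next window when data exist
there. Windows with no source minutes of a kind yield a missing
probability, which propagates as missing (never as 0) into group means
and Δ-contrasts.

Two state bases are offered. The default, `activity`, transitions between
raw active/non-active minutes with activity defined as *any* locomotion
(dist > 0), the standard convention for these statistics. The
alternative, `sleep_state`, uses the 5-min-rule sleep/wake states. Both
are legitimate readings of the published descriptions of P(doze)/P(wake);
neither is asserted as canonical.

When recovering the underlying chain parameters from data, pool the
exported counts (Σ transitions / Σ sources) rather than averaging raw
per-window ratios: a 30-min window holds few source minutes, and the
ratio of small random counts is biased upward (for a chain at
p_wake = 0.3 with ~7 inactive sources per window, the naive window-mean
overshoots by ~0.08 while the pooled estimate is accurate to ~0.003 at
200 flies × 12 h). The counts are exported precisely so users can pool.

## Courtship memory

SI = 100·(1 − median CI⁺ / median CI⁻), in percent. SI is undefined when
the naive median is 0; the observed-data path raises an explicit error
rather than returning ±∞.

Permutation tests (the core statistic of the package):

* **H₀: SI = 0.** Trained and naive CIs are pooled and randomly
  re-assorted into groups of the original sizes; an SI is computed for
  each of n_perm (default 100,000) permuted datasets, and
  p = (1 + #{|SI_perm| ≥ |SI_obs|}) / (n_perm + 1). The add-one
  correction keeps p valid and strictly positive.
* **H₀: SI_exp = SI_ctrl.** Statistic SI_exp − SI_ctrl; the null shuffles
  experimental/control arm labels independently within the trained pool
  and within the naive pool, preserving group sizes. The trained/naive
  structure is not under test, so it is preserved.

Numerical conventions: the pool is sorted before permuting, so p depends
only on the multiset of values, not input order; permutations are
independent random shuffles (not exhaustive enumeration), seeded through
one `numpy.random.Generator`. A *permuted* dataset whose naive group has
median 0 gets the maximal-suppression sentinel |SI| = 100 (sign from the
trained median) instead of being discarded, keeping n_perm fixed. A
degenerate pool (all values equal) returns p = 1.

Note a property of the two-sided |SI| criterion worth knowing: SI is a
ratio statistic, bounded above by 100 but unbounded below, so for pools
whose two groups are almost completely separated, direction-flipped
permutations produce enormous |SI| and the two-sided p saturates near
0.5. With realistically overlapping CI distributions this does not
arise; the type-I calibration of the test at nominal α = 0.05 is
0.046–0.055 in our simulations (Beta-distributed CIs, 40 flies/group,
n_perm = 2,000), and the implementation agrees with a brute-force
permutation oracle to resampling noise.

## Luminescence reporter

Per plate: background = pointwise mean trace of the empty wells
(≥ 1 required, < 3 warned), subtracted from every well; negative
corrected values are allowed. The normalization scalar s is the
time-mean of the pointwise-mean *naive* corrected trace over the full
recorded session (a scalar, not a per-time-point vector — the
"mean of the average trace" reading; a sub-window can be configured).
nlum = corrected/s, so the naive grand mean is exactly 1 and corrected
traces are invariant to plate-wide additive offsets and multiplicative
gain. s ≤ 0 (signal at or below background) is an error. TP1-3 well
means use samples with t ∈ [60, 180) min — exactly 8 points on the
15-min grid — and groups are compared with a two-sided Student t test.
Traces from different training durations are aligned at the end of
training (t = 0). A dead-well QC rule exists but is off by default.

## Calcium imaging and connectivity calls

ΔF/F = (f(t) − F₀)/F₀ with F₀ = mean f over the session's first 10 s —
the pre-stimulus window of the 6-pulse protocol (five-second pulses,
first onset at 10 s, 30-s onset intervals, 200-s session). Per-epoch
re-baselining is available but off by default. Epoch averaging resamples
each onset-aligned segment to a common grid by nearest sample at the
native sampling step and averages pointwise.

Connectivity calls compare per-fly baseline ΔF/F (t ∈ [0, 10 s)) against
per-fly stimulated ΔF/F (union of the six pulse intervals) across ≥ 3
flies, two-sided. The comparison is **paired** within fly by default
(baseline and stimulated values come from the same fly); an unpaired
mode is available. `test='auto'` picks Student t vs Wilcoxon by a
Shapiro normality check at 0.05; both are directly selectable. Direction
is excitatory/inhibitory for p < α (default 0.05) with the sign of the
mean effect, else none. Negating a trace flips the direction with
identical p. Spontaneous activity is simply the mean raw fluorescence
over a 60-s span.

## Connectome filtering

Directed single-neuron edges with integer synapse counts; the threshold
is **inclusive** (weight ≥ 9 retained — "a threshold of 9" read as the
minimum retained count; configurable, and results should be reported
with the threshold used). Survivors are grouped by (pre-type,
post-type) with total weight and retained-pair counts; type pairs with
no surviving pair are absent, not zero. Reciprocal edges are never
merged. Rows with missing type labels are excluded with a warning.

## Synthetic-data generators

All generators take a seed (or Generator) that fully determines output,
and return planted ground truth.

* **Locomotion.** Per-minute active/inactive states follow a two-state
  Markov chain with per-minute P(doze) = P(active→inactive) and
  P(wake) = P(inactive→active); defaults (0.1, 0.3) give a stationary
  inactive fraction of 0.25, a realistic daytime level for single-housed
  males. Time-windowed overrides plant effects (e.g. deepening to
  (0.3, 0.1) confined to TP1-3). Active minutes draw a per-minute
  distance from a log-normal law (median 6 mm, log-SD 0.2 — comfortably
  above the 3.6 mm threshold, so scored activity matches the generating
  state ~99.5% of the time), spread evenly over the minute's frames;
  inactive minutes emit zero. `sim_training_cohorts` builds the
  training-duration experiment: cohorts of 45 flies (matching typical
  published cohort sizes of ~40–50) per duration 0/1/2/4/6 h over a 3-h
  post-training session, with deepening planted only in TP1-3 of the
  4-h and 6-h cohorts.
* **Courtship.** CIs are 100·Beta(a, b) with a + b = 6 (a realistic
  spread for 10-min courtship tests) and a chosen so the Beta median
  approximation (a − 1/3)/(a + b − 2/3) hits the target median; defaults
  30% trained / 80% naive, i.e. a planted SI of 62.5%.
* **Luminescence.** Empty wells: AR(1) noise (φ = 0.5, SD 10 a.u.)
  around a 20 a.u. background. Fly wells add a 100 a.u. reporter level;
  experienced wells add a Gaussian-in-time bump centered 2 h
  post-training (SD 45 min) whose amplitude follows one of three
  training-duration laws: *linear* growth, *peaked* at 2 h, or *step*
  (zero below 4 h) — emulating the three qualitative activity profiles
  the pipeline is meant to distinguish.
* **Calcium.** f = f₀·(1 + r(t) + noise), with r(t) a pulse-locked
  kernel rising as A·(1 − e^(−Δt/τ_rise)) during each pulse and decaying
  exponentially after offset (τ_rise 1 s, τ_decay 4 s, Gaussian noise SD
  0.05 ΔF/F units, ~1 Hz volume rate). The signed amplitude A sets the
  connection direction; the kernel is linear in A.
* **Connectome.** Planted (pre-type → post-type) edges give every neuron
  pair a Poisson(20) weight; every other ordered type pair contributes
  sparse Poisson(2) noise pairs. At the 9-synapse threshold this yields
  type-level precision and recall ≥ 0.95.

What the generators do **not** emulate: circadian modulation and
light/dark structure of sleep, bout-duration heavy tails, per-fly random
effects (all flies of a cohort are exchangeable), tracker artifacts
(jitter, identity swaps, dropped frames beyond the invalid-minute
mechanism), plate-position effects and luciferin depletion, calcium
indicator nonlinearity and bleaching, and connectome reconstruction
biases. Passing tests therefore certify the *analysis* chain — its
conventions, statistics and invariances — not robustness to every
artifact of real recordings.

## Problem sizes in the test and verification suites

The verification scripts use 1,000 random minute strings for the
scoring oracle, 200 flies × 12 h for transition-probability recovery,
1,000 null datasets at n_perm = 2,000 for permutation calibration, 200
simulations per regime for connectivity-call recovery, and 100
replicates of the 5-cohort training experiment for the end-to-end
pattern — sizes at which Monte-Carlo error is small relative to every
tolerance checked while the whole suite stays comfortable to run on a
laptop.

## Known limitations

* **ΔSleep significance testing is anti-conservative by construction.**
  Per-fly ΔSleep subtracts the *same* control-cohort mean from every
  experimental fly, so all deltas share the control mean's sampling
  error (variance σ²/n_ctrl), which a one-sample signed-rank test —
  treating deltas as independent — does not account for. The effective
  z-variance is inflated by 1 + n_exp/n_ctrl; at equal cohort sizes the
  true type-I error at nominal α = 0.05 is ≈ 2·Φ(−1.96/√2) ≈ 0.17,
  independent of cohort size, and our end-to-end simulations reproduce
  exactly this (~0.83–0.86 of null replicates above p = 0.05). This is a
  property of the standard ΔSleep procedure itself, which the package
  reproduces faithfully; it matters whenever single-group "ΔSleep ≠ 0"
  p-values near the threshold are interpreted. Between-group rank-sum
  comparisons of ΔSleep are unaffected (the shared offset cancels), and
  genuinely large effects (as in the planted 4-h/6-h cohorts) are
  unambiguous. A paired or hierarchical design, or inflating the control
  cohort, would restore nominal calibration — at the cost of departing
  from the established procedure.
* The between-arm permutation scheme (shuffling arm labels within
  condition) is a declared design choice; other exchangeability schemes
  exist and published analyses rarely print theirs.
* `connectivity_call`'s `auto` test selection pre-tests normality, which
  perturbs the nominal level slightly (null "none" rate ~0.91–0.96 in
  simulation at n = 7 flies).
* Epoch averaging uses nearest-sample alignment, appropriate at the
  ~1 Hz volume rates it targets; sub-sample interpolation is out of
  scope.
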