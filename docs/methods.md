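# Methods

## The screening problem and the post-hoc design

A screener assigns status 'eligible' when the sum score S over J
polytomous items reaches a cutoff t.  All experiments here are *post-hoc
simulations*: an adaptive algorithm is replayed against complete observed
responses, each respondent's answer to any item being looked up in their
recorded row, and the complete-data status S ≥ t is treated as the truth
against which predictions are scored.  This design needs complete data;
missing responses are rejected at I/O rather than imputed, because an
imputed "truth" would contaminate the validity criterion.

## Latent class engine

The unrestricted latent class model (ULCM) places K latent classes with
weights π over respondents; within a class, item scores are independent
categoricals ρ_{kj}.  The model is deliberately unrestricted — no
ordering or monotonicity constraints — because for screening we need the
joint pattern distribution, not an interpretable trait.

Estimation is EM on unique response patterns (a large computational win
on survey data, where low-severity patterns repeat thousands of times).
Numerical choices:

- **Starts**: π and ρ drawn from mildly concentrated Dirichlets, 20
  random starts by default (10 inside the experiment harness).  ULCM
  likelihoods are multimodal; the best final log-likelihood wins.
- **Convergence**: absolute log-likelihood gain < 1e−8, max 1,000
  iterations.  The winning start's trace is kept on the fitted object so
  monotonicity is checkable after the fact.
- **Probability floor**: ρ entries are floored at 1e−10 in every M-step
  (then renormalized) so a category unobserved within a class cannot
  produce log 0 on later data.
- **Label switching**: class labels are arbitrary.  Nothing downstream
  depends on them; recovery tests match classes by best permutation.
- **K selection**: BIC = −2 logL + p ln N over K = 1..max_classes, with
  p = (K−1) + K Σ_j (m_j−1).  A K that fails to fit is recorded in the
  BIC table and skipped, not fatal.
- K = 1 is computed in closed form (observed marginals); requesting more
  classes than distinct patterns warns about non-identification but
  still returns.

## Eligibility probability

The quantity driving administration is q = P(S ≥ t | answered items).
Two routes are implemented:

1. **Class-posterior + convolution** (production): Bayes gives
   P(k | answered) ∝ π_k Π ρ_{kj}(x_j); within class k the remaining
   items' sum distribution is an exact dense convolution over the
   integer support (≤ 27 for a PHQ-9-like bank, so no FFT is needed);
   q is the posterior-weighted tail mass.  Cost is linear in the bank.
2. **Pattern enumeration** (oracle): literally enumerate all completions
   of the observed fragment, drop obsolete patterns, renormalize and sum
   those reaching the cutoff.  Exponential in the remaining bank — the
   enumerator refuses more than 10^6 completions, which is exactly the
   memory wall that makes route 1 necessary for larger banks.

The two are mathematically identical; the test suite asserts agreement
to 1e−10 on random models, and the martingale property (the expected
next-step q equals the current q under the model's predictive
distribution) to the same tolerance.

Deterministic states are kept exact: q is returned as precisely 1.0 when
the partial sum already reaches the cutoff and precisely 0.0 when even
maximal remaining scores cannot, while any genuinely uncertain q is
clipped into (0, 1) by 1e−15.  Exact 0/1 thereby *certifies* a
deterministic state, which is what makes the c = 1.0 stopping rule
provably error-free rather than error-free up to float rounding.

## Administration and item selection

Items are administered one at a time; the test halts when q ≥ c
('eligible') or q ≤ 1 − c ('not eligible').  Choices:

- **Non-strict comparison** (≥ c rather than > c): with discrete
  responses, exact ties at c are possible and a reproducible convention
  is preferable.
- **Minimum one item** is always administered, even when the prior alone
  would pass c — a screener that asks nothing is not a screener.
- **Fallback**: if all J items are used without triggering, the decision
  is the observed sum vs the cutoff (q is exactly 0/1 at that point).
- **Selection rule** (default): administer the item minimizing
  E[min(q', 1−q')], the expected posterior uncertainty of the
  eligibility indicator over the candidate item's predictive response
  distribution.  This targets the screening decision directly rather
  than measurement precision.  The expectation is computed exactly using
  leave-one-out convolutions (prefix/suffix products over the remaining
  items).  The selection literature offers several defensible rules;
  this one is the package's design choice, and the strategy argument is
  pluggable — "fixed" (questionnaire order, which reduces LSCAT to an
  SC-like scheme) and "random" ship for ablation.  Ties break to the
  lowest item index.
- **Caching**: for deterministic strategies both the next-item choice
  and q depend only on the set of (item, score) pairs observed, so a
  sample-level administrator memoizes them; respondents sharing a prefix
  share the work, collapsing survey-scale administration to the number
  of distinct partial patterns visited.

## Stochastic curtailment

Fixed item order (the questionnaire's printed order by default).  For
each step k = 1..J−1 a logistic regression of true status on the
cumulative score s_k is fitted on calibration data; the fitted curve is
inverted on the integer grid into stop thresholds (smallest s_k with
p̂ ≥ γ → 'eligible'; largest with p̂ ≤ 1−γ → 'not eligible').
Deterministic curtailment bounds always dominate: s_k ≥ t stops
'eligible' at any γ, and s_k below t minus the maximal remaining score
stops 'not eligible'.  A separated or degenerate regression falls back
to the deterministic bounds with a warning (status on cumulative score
is the minimal model consistent with a cumulative-score look-up table;
richer predictors are out of scope).  As γ → 1 the logistic thresholds
become unreachable and SC reduces to purely deterministic curtailment,
which makes zero classification errors — a limit the tests exercise.
The regressions are γ-free, so efficiency matching fits them once and
re-thresholds per γ.

## Decision-tree CAT

A single CART classification tree (Gini impurity, ordinal threshold
splits on item scores, cost-complexity pruning) is grown by scikit-learn
on the calibration sample with status as outcome, then extracted into an
explicit node structure for administration.  The internal criterion
(status from the sum score) is the outcome, matching the post-hoc
design.  Defaults: minimum leaf size 50 (stabilizes leaf labels at
survey scale; exposed), pruning parameter 0 unless tuned.  Items are
counted once per path even if split twice.  A degenerate single-leaf
tree would ask no items; it is flagged (n_items = 0, stopped_early) and
warned at fit time rather than silently reported as an administration.
Alternative pruning schemes that balance branch sizes exist in the
decision-tree screening literature; standard cost-complexity pruning is
used here and results should not be read as replicating those variants.

## Efficiency matching and evaluation

Within each (cutoff, criterion) design cell, LSCAT's average number of
administered items *on the calibration sample* is the efficiency target;
SC's γ and DTCAT's pruning parameter are then chosen from grids as the
points whose calibration-sample averages come closest (ties to the
cheaper point).  Tuning never sees validation data.  Exact equality is
unattainable on discrete data, so the achieved average and the gap are
reported in the tuning log rather than hidden; gaps of a few tenths of
an item are normal.  The γ grid densifies toward 1 (0.55..0.99 in steps
of 0.01, then 0.993..0.99999) because high-cutoff cells need very
conservative stopping before SC's average moves.

Validity metrics against complete-data status: Type I = FP/(TN+FP),
Type II = FN/(TP+FN), Accuracy = (TP+TN)/N, Cohen's κ with chance
agreement from the marginal products.  Accuracy alone is misleading at
a ~24% base rate, hence κ alongside; κ bands ("moderate", "almost
perfect", …) are attached as report labels only.  Undefined ratios (no
actual positives/negatives, chance agreement 1) are NaN with a flag,
never silently zero.  The base-rate benchmark draws Bernoulli(base rate)
predictions as the random-assignment floor; its κ is ~0 by construction.
The identity Accuracy = 1 − (TypeI·w_neg + TypeII·w_pos), with w the
actual status proportions, is asserted numerically in the tests.

The data split is an unstratified uniform 50/50 permutation (calibration
gets the ceiling); a stratified option exists behind a flag but
stratification is not the default because the base rates are high enough
(9–24%) that both halves are well populated at survey scale.

## Synthetic data

The generator samples class ~ π then scores ~ ρ; with a specified model
it is exact by construction, and the sidecar returns class, sum and
status ground truth.  The PHQ-9-like preset is a three-class mixture
(asymptomatic 58.5%, mild 31%, elevated 10.5%) over nine four-category
items, with per-item endorsement tilts making items 2–4 more endorsed
and the last items less.  Its base rates are *model-implied*: computed
by exact convolution, P(S ≥ 5) = 0.240, P(S ≥ 10) = 0.091, E[S] = 3.10,
skewness ≈ 1.9 — calibrated once against the convolution (not against
samples), so they hold for every seed.  These match the structure of
general-population depression screening data: about a quarter at least
mildly and about a tenth at least moderately symptomatic.

What the preset does **not** emulate: real survey dependence beyond a
3-class mixture (local dependence, severity gradients finer than three
groups), item wording effects, survey weights, demographics.  Passing
tests on the preset therefore demonstrate the correctness and the
comparative behaviour of the algorithms under a realistic marginal
structure, not the exact error rates any particular real dataset would
produce; the harness accepts real response CSVs for that purpose.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run the full comparison at
N = 20,000–20,685 respondents (split 50/50), EM recovery and stopping
calibration at n = 10,000, and the oracle suites on 100 random small
models (K ≤ 4, J ≤ 6) — sizes at which every stochastic check is stable
across seeds while the whole suite stays fast.

## Known limitations

- The eligibility computation is exact but the engine is only as good as
  the fitted ULCM; no online recalibration is provided.
- The enumeration oracle (and hence the literal pattern-table method) is
  limited to ~10^6 completions; the convolution route has no such limit
  but the selection rule's leave-one-out pass is O(J²) per state, which
  is negligible at J ≤ 15 and untested far beyond.
- SC is implemented in its status-on-cumulative-score form; variants
  regressing on richer predictors are out of scope.
- No significance testing or confidence intervals accompany the validity
  tables; the harness compares point estimates, as is standard for
  efficiency-matched CAT comparisons.
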