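# Methods

## Models

Both models operate on N×M matrices of integer ratings 0..L with missing
entries, and express everything through γ_ij = β_i − δ_j (person minus
item, logits).

**Ordered-threshold model (the one MSD estimates).** A rating scale is a
real line cut by strictly ordered thresholds τ_1 < … < τ_L into L+1
half-open categories, closed on the left: C_0 = (−∞, τ_1), C_h = [τ_h,
τ_{h+1}), C_L = [τ_L, ∞). On a trial the respondent's comparison value is
γ plus a combined deviate; the rating is the category containing it. With
a logistic deviate distribution (the unique choice under which the L=1
case is the dichotomous Rasch model),

    P(rating ≥ h) = σ(γ − τ_h),  σ(x) = 1/(1+e^{−x}),
    p(C_h) = σ(γ − τ_h) − σ(γ − τ_{h+1})    (boundary terms 1 and 0).

This is a graded-response form with unit discrimination and thresholds
common to all items; discrimination parameters are deliberately absent —
they would put each item on its own scale. Thresholds sit at the 50%
cumulative split: at γ = τ_h exactly half the probability mass lies in
categories ≥ h. Disordered thresholds would make some p(C_h) negative, so
the model excludes them by construction.

**Andrich rating scale model (baseline).** p(C_h) ∝ exp Σ_{q≤h}(γ − τ_q).
Its thresholds sit at crossing points p(C_{h−1}) = p(C_h) and carry no
ordering constraint. Both models coincide at L = 1.

## Estimation

**Dichotomous JMLE** (`jmle_fit`). Alternating damped Newton–Raphson on
the joint likelihood, persons then items, steps clipped at 1 logit,
items re-anchored to mean zero each sweep; convergence when the largest
step falls below `tolerance` (default 1e−6 logits, max 1000 sweeps).
Rows/columns with extreme observed scores (all 0 or all 1) have no finite
MLE; they are excluded *iteratively* (an exclusion can expose new extremes)
and reported. Information-based standard errors 1/√Σp(1−p). No
finite-sample bias correction is applied.

**MSD** (`fit`). Dichotomize at h = 1..L, JMLE each D_h, average the
per-level person and item measures, re-anchor items to mean zero (the
same shift applied to persons so γ is untouched), then estimate each τ_h
by a one-parameter MLE on D_h with measures fixed — the score function is
monotone in τ, solved by bracketed root finding in [−10, 10] (expanded if
needed), SE from the observed information. Each dichotomous fit estimates
β_i − τ_h, so the averaged persons and the fitted thresholds share an
origin of minus the mean threshold; items are anchored at mean zero. All
recovery statistics reported here are invariant to that common shift.

Ordering of the estimated thresholds is structural, not imposed: D_h is
pointwise ≤ D_{h'} for h > h', and all threshold fits share the same
fixed measures, so the MLE roots strictly increase in h whenever the
dichotomizations differ.

Persons excluded at some levels (extreme on that dichotomization only)
are averaged over the levels where they have estimates. Their averages
carry a partial origin (the mean of the *available* thresholds), a known
bias of order (τ̄_missing − τ̄)/L that is visible when comparing against a
simultaneous MLE on very small matrices; with 100 items it is absorbed
into the reported recovery correlations. Wholly extreme persons get NaN.

Person/item standard errors follow the spread rule: SD over levels of
(b_i(h) − τ̂_h), divided by the number of levels the person appears in;
`se_divisor="sqrt"` divides by its square root instead (the conventional
standard-error scaling) — the default divisor is kept as the method
defines it. At L = 1 the spread is undefined and the information-based
SEs are reported with a warning.

**Andrich JMLE** (`andrich_jmle_fit`). Gauss–Seidel damped Newton over
three blocks per sweep — persons, items, thresholds — each from a fresh
probability evaluation (updating blocks simultaneously from one
evaluation enters a limit cycle at the reference scale). The threshold
block solves the full L×L observed information (Σ over cells of
Cov(1[X≥q], 1[X≥r])); with many thresholds the diagonal alone leaves
slowly decaying coupled modes. Anchors: mean item
zero, thresholds sum to zero. Thresholds are reported exactly as
estimated, with flags on each adjacent pair where τ̂_h ≥ τ̂_{h+1}.
Initialization: logits of relative raw scores; thresholds at minus the
logit of the cumulative response proportions.

## Simulator

The generator emulates a rating study in which every trial uses its own
strictly ordered threshold set:

* β, δ, τ ~ Uniform[−2, 2] (δ centred to mean zero; τ sorted after
  drawing). Defaults: N=1000, M=100, L=9, 10% missing at random.
* Per-trial threshold sets for all K = N·M trials by
  correlate-then-decorrelate: add one N(0, 1) deviate per set to the
  threshold means (ordered, perfectly correlated sets), then attempt K·L
  random swaps of a single threshold between two random sets, accepting a
  swap only if both sets stay ordered. Swaps permute values within a
  threshold, so each threshold's marginal distribution is preserved
  exactly while cross-set correlation decays. Rejection sampling would
  skew the marginals, which is the reason for this construction.
  Sets are assigned to trials sequentially by trial index k = i·M + j.
* Rating on trial k: v = β_i − δ_j + ε, ε ~ N(0, 1); the rating is the
  number of thresholds in set k at or below v (half-open convention: v
  exactly at a threshold takes the category it opens).
* Between-person threshold differences are not simulated: neither model
  can separate them from shifts in the person measures.

The combined error variance is therefore 2 (trial noise plus threshold
deviates, both unit normal). The model assumes a logistic combined
deviate with variance π²/3; estimating on data with error SD √2 stretches
the recovered scale by the ratio of the two, a = π/√(3·2) ≈ 1.2825 — the
analytic slope `predicted_slope(2)` — and measured estimated-versus-true
slopes land near 1.25, slightly under the prediction because the error
shape is normal rather than logistic.

What the simulator does *not* emulate: response styles, person misfit,
multidimensionality, differential item functioning, informative
missingness. Passing recovery tests therefore demonstrates correctness of
the estimators under the model's own assumptions, not robustness to
violations of them.

## Replication experiment

`run_replication_study` simulates once at L=9 and fits both models; while
more than one threshold remains it merges one adjacent category pair and
refits both models on the rescored data, carrying the true thresholds
through each merge by deleting the removed one. The merge rule is
deterministic: remove the upper threshold of the adjacent pair with the
largest Andrich reversal τ̂_h − τ̂_{h+1} (once no pair is reversed this
picks the narrowest pair). Conditions run down to L=1 — the dichotomous
endpoint where both models coincide — giving nine conditions; pooled
cross-condition statistics use the eight polytomous ones, and the mean
estimated-versus-true item slope averages all nine.

Pooling concatenates each condition's estimates against the repeated true
values. MSD person estimates carry a per-condition origin (minus the mean
of that condition's surviving thresholds), so pooled person r² sits below
the within-condition values; item estimates are always anchored at mean
zero and pool near-perfectly. The Andrich baseline additionally changes
*scale* across conditions (its item-slope rises as categories are
merged), which is what drags its pooled person r² far below MSD's.

## Diagnostics

* `recovery_summary`: Pearson r, r², and OLS slope/intercept of estimates
  regressed on truth (that direction defines "slope" throughout); NaN
  estimates dropped pairwise.
* `infit_mean_squares`: per person, Σ(r−E)²/ΣVar over observed items,
  with E and Var from the fitted model's category distribution. The
  reference distribution is the mixture over persons of χ²_df/df at each
  person's own observed count (df varies with missingness). Under the
  generator mean person infit is ≈ 1; the empirical and reference CDFs
  track each other with a small tail separation (~0.06 max at reference
  scale) attributable to the normal error shape.
* `probability_curve_data`: bins observed cells by a caller-supplied γ
  (0.2-logit bins by default) and tabulates observed category fractions
  against the model curve at the bin midpoint. Bins under 10 observations
  are excluded from the summary discrepancy — their binomial noise
  swamps any signal; the consistency checks here use a 200-observation
  floor.

## Numerical choices and edge cases

* Probabilities via `scipy.special.expit`/`softmax` (log-space), stable
  past |γ−τ| = 700.
* Newton steps clipped at 1 logit; JMLE tolerance 1e−6 logits.
* Threshold root bracketing starts at [−10, 10] and doubles to ±40 before
  declaring divergence (one-sided dichotomizations raise instead).
* Unused categories raise: for MSD two dichotomizations would coincide
  and their thresholds tie; for Andrich the threshold is inestimable.
* Category boundaries in the simulator are closed on the left; a trial
  value exactly at τ_h gets category h.
* Tiny matrices can violate the connectivity condition for JMLE existence
  (estimates drift; the iteration limit then raises with the last
  iterate attached). Zero-noise simulation produces perfect Guttman
  patterns with no finite MLE at all — deterministic-limit behaviour is
  checked on the simulator side, not the estimator side.

## Known limitations

* JMLE is inconsistent at fixed M (incidental parameters); no (N−1)/N-type
  correction is applied, matching the comparison design.
* Partial-exclusion origin bias for persons missing from some
  dichotomizations (above).
* The person-SE divisor L is unconventional (SD/√L is the usual standard
  error); both are available, the default follows the method's
  definition.
* The Andrich threshold-recovery correlation at L=9 under this generator
  is a near-zero, on-average-negative quantity; its sign on any single
  run is sampling noise (measured across runs it averages ≈ −0.07).
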