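# msdrasch

Rating-scale measurement by the **Method of Successive Dichotomizations
(MSD)**: estimation of person measures, item measures and *strictly
ordered* category thresholds from polytomous rating data, with an Andrich
rating-scale-model baseline, a simulator for ordered-per-trial-threshold
data, and recovery/fit diagnostics.

## The problem

Patient-reported outcomes and clinician ratings (disability indices,
symptom severity scales, quality-of-life questionnaires) are ordinal: each
of N persons assigns each of M items a category 0..L. Conjoint measurement
models place persons (β, the latent trait), items (δ, sensitivity) and
category boundaries (τ, thresholds) on a common logit scale and estimate
them from the rating matrix.

A rating scale is, by definition, a real line partitioned by *ordered*
thresholds into ordered categories — so no estimator should produce
disordered thresholds. The widely used Andrich rating scale model
nevertheless often does, and its users are advised to merge categories and
refit until thresholds come out ordered; merging also silently changes the
scale of the resulting measures. The model implemented here takes the
ordered partition seriously: with γ = β − δ,

    P(rating ≥ h) = exp(γ − τ_h) / (1 + exp(γ − τ_h)),         τ_1 < … < τ_L
    p(C_h)        = P(rating ≥ h) − P(rating ≥ h+1)

a graded-response form with unit discrimination and thresholds common to
all items. Disordered thresholds would give negative probabilities, so the
model cannot produce them; and because each τ_h is defined by the 50%
cumulative split, merging categories leaves all other parameters invariant
(up to the origin).

## Estimation: successive dichotomizations

MSD reduces the polytomous problem to L dichotomous Rasch fits:

1. for each h = 1..L, form the 0/1 matrix D_h = [r_ij ≥ h] and fit the
   dichotomous Rasch model by JMLE;
2. average the L person measures per person and the L item measures per
   item (items re-anchored to mean zero);
3. with measures fixed, estimate each τ_h by a one-parameter MLE on D_h.

Because the D_h are nested and every threshold is fit against the same
fixed measures, the estimated thresholds are always strictly ordered.
Standard errors: SD over h of (b_i(h) − τ̂_h) divided by L for persons
(`se_divisor="sqrt"` selects SD/√L), likewise from d_j(h) for items, and
inverse-root observed information for thresholds.

## Worked example

```python
import numpy as np
import msdrasch as m

cfg = m.SimulationConfig(n_persons=200, n_items=20, n_thresholds=4,
                         seed=20260930)
R, truth, _ = m.simulate(cfg)          # 200x20 ratings 0..4, 10% missing
fit = m.fit(R)                         # MSD estimates
print(np.round(fit.thresholds, 3))
print(m.recovery_summary(fit.item_measures, truth.item_measures, "item"))
```

prints

```
[-0.987 -0.513  0.246  1.44 ]
RecoverySummary(parameter_kind='item', n=20, pearson_r=0.9951827068364048,
r_squared=0.9903886199862335, best_fit_slope=1.3574913746112345,
best_fit_intercept=5.551792254332067e-17)
```

The thresholds are strictly increasing; item measures correlate with the
generating truth at r² ≈ 0.99, and the slope ≈ 1.36 reflects the scale
stretch produced by the simulation's combined error variance (see
`docs/methods.md`). The same data fit with the Andrich baseline
(`m.andrich_jmle_fit(R)`) gives thresholds `[1.208, -0.785, -0.3,
-0.122]` — disordered, on clean simulated data.

From the shell:

```
msd simulate --seed 1 -o sim/            # ratings.csv + truth.json
msd fit sim/ratings.csv -o fit/          # persons/items/thresholds tables
msd fit --model andrich sim/ratings.csv -o fit_a/
msd diagnose sim/ratings.csv fit/ --truth sim/truth.json -o diag/
msd replicate --seed 1 -o rep/           # full successive-merge study
```

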