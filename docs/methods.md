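# Methods

This note documents the models, default parameters and numerical choices
behind `novascore`, and what the synthetic studies do and do not
demonstrate.

## The knowledge score

Within each category triad the scorer evaluates the three ordered pairs
r(G1) > r(G3), r(G1) > r(G4), r(G3) > r(G4) strictly. Three correct pairs
earn 2 points, exactly two earn 1, fewer earn 0; totals sum over complete
categories only. Two points of the rule are genuinely underdetermined by
its usual prose statement, and both are explicit policy switches:

- **Ties** (`tie_policy`). The published rule says tied ratings earn no
  points but not whether a tie voids the pair or the whole category. The
  default, `pair_incorrect`, is the minimal reading: only the tied pair is
  incorrect, so ratings 9/9/2 still earn 1 point from the two strict pairs
  against the G4 item. `zero_category` voids any category containing a tie.
- **Single correct pair** (`one_pair_policy`). The 1-point clause describes
  exactly-two-correct configurations (e.g. G1 > G4 > G3). Orderings with
  one correct pair (e.g. G3 > G4 > G1) fall outside every stated clause;
  the default awards 0, `one_point` awards 1.

Neither switch affects the canonical worked orderings (2 / 1 / 0 points).
Ratings must be integers on the instrument scale; a respondent with any
missing rating gets an incomplete category and no total (`missing_policy`
offers no prorating variant — partial totals are never comparable across
respondents). No imputation is ever performed.

## Synthetic rating model

Each respondent has a latent knowledge level k ∈ [0, 1], drawn from a
normal distribution truncated to [0, 1]. Nova groups carry latent
healthiness means on the rating scale (G1 = 9, G3 = 6, G4 = 3; mean
m̄ = 6), and the rating of an item in group g is

    clamp(round(m_g·k + m̄·(1 − k) + ε)),  ε ~ N(0, noise_sd²).

k = 1 with no noise reproduces the hierarchy exactly (total 8); k = 0
erases group separation, leaving i.i.d. ratings whose expected score is the
enumeration-computable chance level. Expected score is monotone in k. This
is a deliberately minimal one-parameter construct — it emulates the trait
the score measures, not respondent cognition; real response styles
(end-of-scale anchoring, category-specific familiarity, correlated errors
across items) are absent, so passing recovery tests here says the
*pipeline* is correct, not that the instrument is valid in any population.

**Calibration.** The bundled scenarios were calibrated once by grid search
on large simulated samples to the group summaries the validation design is
built around, then frozen:

| scenario  | k ~ TN(mean, sd) | noise_sd | totals: mean (SD) | target |
|-----------|------------------|----------|-------------------|--------|
| nutrition students (n=76) | (0.80, 0.15) | 1.2 | 6.75 (1.07) | 6.7 (1.1) |
| education students (n=99) | (0.485, 0.02) | 1.3 | 5.31 (1.30) | 5.3 (1.2) |
| cohort (n=1,245)          | (0.478, 0.02) | 1.1 | 5.60 (1.22) | 5.6 (1.2) |

At a mean total near 5.3 the per-category pair comparisons are themselves
highly stochastic, so the model's intrinsic total-score SD is already ≈1.3;
the comparison-group SD therefore cannot be brought below ≈1.3 without
changing the rating model, and latent heterogeneity there is near zero.
Covariate distributions (sex, age, education) follow the corresponding
study descriptions and are independent of k by default; the
`confounder` hook exists for sensitivity experiments but is off because no
score–covariate dependence structure is documented for these samples.

## Recall and intake model

True usual UPF intake is linear in the total score,
u_i = 27.4 − 1.03·score_i + b_i with b_i ~ N(0, 9.0²), truncated to
[0, 100]. The intercept places the cohort mean at 21.6% of energy at the
calibrated mean score (27.4 = 21.6 + 1.03·5.6) and sd_between = 9.0 puts
the total usual-intake SD at ≈9.1 including the score-driven component.
Each person completes 1, 2 or 3 recalls with probabilities 0.105 / 0.178 /
0.716 (printed survey-completion proportions; they sum to 0.999 and are
renormalised at draw time), observed as y_ij = u_i + w_ij,
w_ij ~ N(0, sd_within²), truncated to [0, 100]. Truncation rather than
resampling keeps the generator simple; at these SDs the truncation mass is
negligible (the mean shifts by ≪ 0.1 %-point).

`sd_within` defaults to **4.0 %-points**. This is a deliberate choice tied
to the estimator below: the simplified shrinkage estimator pulls person
means toward the *grand* mean, which attenuates any regression on the
shrunken values by roughly the mean shrinkage factor λ̄. At sd_within = 4
and sd_between ≈ 9, λ̄ ≈ 0.92 and the attenuation of the score slope
(≈0.08·1.03 ≈ 0.08 %-points) stays inside its sampling error at n = 1,245,
so the convergent analysis remains approximately unbiased. Real day-to-day
variation in UPF% of energy is typically larger (within-person variance
can exceed between-person variance); under such noise a grand-mean
shrinkage estimator visibly attenuates associations, and the
covariate-aware shrinkage of a full usual-intake method is needed. This is
a known limitation of the simplified estimator, not of the score.

## Usual-intake estimation

One-way random-effects method of moments: pooled within-person variance
σ̂²_w = SSW/(N−k); between mean square MSB = SSB/(k−1); effective replicate
count n₀ = (N − Σn_i²/N)/(k−1) for the unbalanced 1–3-recall design;
σ̂²_b = max(0, (MSB − σ̂²_w)/n₀), truncating negative moment estimates to
zero with a warning. Per person,

    λ_i = σ̂²_b / (σ̂²_b + σ̂²_w / n_i),
    usual_i = grand_mean + λ_i·(person_mean_i − grand_mean).

λ_i ∈ [0, 1] and increases with the recall count; σ̂²_w = 0 gives λ = 1
(estimates are the person means), σ̂²_b = 0 gives λ = 0 (everyone at the
grand mean — the degenerate 0/0 case resolves the same way since all
person means then coincide in expectation). The estimator needs ≥2
respondents and ≥1 respondent with ≥2 recalls; anything less raises an
identifiability error rather than returning a silent zero.

This is the shrinkage core of usual-intake estimation only. The Multiple
Source Method additionally models covariates, applies a Box–Cox
transformation, and handles episodically consumed foods; none of that is
implemented, and no equivalence with MSM output is claimed. UPF% of energy
is near-continuous and every respondent consumes some, which is why the
two-part and transformation machinery can be dropped for this use.

## Statistical battery

- **Mann-Whitney** (two-sided, U for the first sample, midrank ties): exact
  distribution when both n ≤ 10 and there are no ties; full enumeration of
  group assignments when `exact=True` is forced on tied data; otherwise the
  normal approximation with tie-corrected variance and continuity
  correction. The exact path is capped at ~2·10⁶ assignments.
- **2×2 chi-square** with Yates continuity correction on by default — the
  corrected statistic reproduces the comparability p-values the two-student
  design prints (0.064 for sex, 0.121 for education), indicating the
  original analysis used it; `continuity=False` recovers the classical
  n(ad−bc)²/(row·col products) statistic.
- **Welch t from summaries** with Satterthwaite degrees of freedom.
- **Adjusted OLS**: usual intake on a score measure plus sex, age and
  education, complete cases, classical SEs. Categorical covariates are
  coded as indicators against the first sorted level (the safest default
  for a 3-level education factor; the score coefficient is invariant to the
  choice). Rank-deficient designs raise an error naming the collinear
  columns; a fit needs at least 10 more observations than parameters.
  In the per-category regression table, category scores enter one model at
  a time with the identical covariate set.
- **Sample size**: n = ⌈(z_{1−α/2} + z_{power})²(sd₁² + sd₂²)/Δ² / ARE⌉
  per group, with ARE = 0.864 the worst-case asymptotic relative efficiency
  of the Mann-Whitney test against the t test. This is a *reconstruction*
  of the planning calculation from its stated inputs (Δ = 0.5, SDs 0.8 and
  1.2, power 0.80, α = 0.05 → 76 per group), documented as such rather
  than as the planners' verbatim method.

All p-values are two-sided; the significance convention is 5%; no
multiple-testing adjustment is applied anywhere (none is used in the
validation design being mirrored).

## Reproducibility and problem sizes

Every generator takes one integer seed; component substreams are spawned
from it, so outputs are byte-identical across runs and adding a component
never perturbs another. Timestamps are excluded from the run-log config
hash so determinism is testable.

The simulation studies run at the design's own sizes — 76/99 for the
two-group study and 1,245 for the cohort — with 500 and 200 seed
replicates respectively in the acceptance suite; those replicate counts
give binomial standard errors below 1.6% on the rates they estimate, which
is sufficient to distinguish the claimed behaviour (rejection >99%,
CI coverage ≈95%) from failure. Measured at those settings: two-group
Mann-Whitney p < 0.001 in 100% of seeds; slope-CI coverage 94%; shrinkage
beat raw person means in all 200 seeds.

## Known limitations

- The rating model cannot emulate response styles or item-level
  familiarity; calibration targets only the first two moments of the
  score distribution.
- The comparison-group score SD has a model floor of ≈1.3 (see above).
- Grand-mean shrinkage attenuates regressions when within-person recall
  noise is large; interpret the convergent analysis accordingly or use a
  covariate-aware usual-intake method.
- Scores and covariates are generated independently, so the adjusted and
  unadjusted synthetic regressions estimate the same slope; adjustment
  matters only on real data.
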