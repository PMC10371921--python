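# Methods

## Model

The analysis targets a two-wave parallel multiple-mediation system: a focal
predictor X (perceived impact of an exclusionary immigration law, 1–9 scale,
wave 1) acting on an outcome Y (global self-esteem, 1–4, wave 2) through three
wave-2 mediators — ethnic centrality (1–5), ethnic private regard and ethnic
public regard — with the wave-1 measures of all four repeated constructs
(U₁…U₄) as lagged covariates in every equation. Mediator equations regress
each Mⱼ on {X, U}; the outcome equation regresses Y on {X, M₁, M₂, M₃, U}; the
total-effect equation regresses Y on {X, U}. Estimation is ordinary least
squares with classical standard errors (HC3 available behind a flag, not the
default, to match the t/df-style inference the design implies). Specific
indirect effects are the products aⱼbⱼ, the total indirect effect their sum.
Because all five equations are OLS on the same completed dataset with matching
covariate sets, c₁ = c′ + Σⱼ aⱼbⱼ is an exact algebraic identity, and it is
preserved at the pooled level because pooling is averaging and indirect
effects are pooled as means of per-imputation products. (The product of
pooled paths is reported alongside for comparison; the two differ by the
covariance of the path estimates across imputations.)

Demographic covariates (age, binary gender, immigrant generation expanded to
two dummies) can be appended; they enter **all** equations uniformly, which
keeps the decomposition identity intact. A sensitivity variant ("own"
covariate set) instead gives each equation only the lag of its own construct;
that variant deliberately breaks the identity and exists for robustness
checks, not for the primary analysis.

## Scale scoring

Scores are prorated item means: reverse-worded items are recoded
v → min + max − v, and a score is produced when at least half the items are
answered (configurable `min_prop_observed`, default 0.5 — the conventional
psychometric proration rule). Cronbach's alpha is computed on
listwise-complete rows as k/(k−1)·(1 − Σ item variances / total variance).

One measurement decision deserves note: the private-regard *scores* are
treated as living on 1–5. The instrument's response anchors are 4-point, but
the reported score means (4.18 and 4.29) are impossible on a 1–4 range, and a
generator truncating at 4 could not reproduce them; 1–5 is the only range
consistent with the descriptive moments.

## Synthetic panel generator

The generator is the package's ground truth and emulates the study
conditions; its defaults are not tuning knobs.

* **Exogenous block.** (X, U₁…U₄) plus four wave-0 auxiliary scores are drawn
  from a 9-dimensional Gaussian and truncated to their scale bounds. The
  latent mean/SD of each variable are solved (2-D root find on closed-form
  clipped-normal moments) so that the **post-truncation** moments equal the
  reported descriptive values — a naive clipped N(4.10, 2.71) on [1, 9] would
  have mean 4.23, so calibration is what makes the generated predictor match
  4.10/2.71 at large n. The latent correlation matrix uses the reported
  bivariate correlations for the wave-1 block; auxiliaries attach with a
  stability correlation of 0.55 via A = 0.55·U + √(1−0.55²)·E (E an
  independent copy with the same correlation structure), which guarantees
  positive definiteness. Truncation shrinks realized correlations slightly
  (up to ~0.06 where ceilings bind).
* **Endogenous block.** Mediators are generated structurally from the default
  true paths (the published coefficient magnitudes: a = (0.019, 0.032, 0.005),
  b = (0.001, 0.117, 0.011), c′ = −0.004, plus the per-equation lagged
  coefficients), with intercepts and residual SDs solved in closed form so
  the *latent* wave-2 means/SDs match the descriptive table. Y is generated
  from the **truncated** mediators, so the b-paths and c′ hold exactly with
  respect to observable data.
* **Truncation and the estimand.** Ceilings bind hard for private regard
  (~15% of latent mass above 5) and public regard (~23% above 4) — a direct
  consequence of the reported moments. Clipping the dependent variable of a
  mediator equation attenuates its a-path roughly in proportion to the
  clipped mass, so a₂ and a₃ attenuate by ~15–20% while a₁, the b-paths and
  c′ move by <10%. The package therefore defines the generator's **estimand**
  as the large-sample complete-data OLS coefficient vector
  (`estimand_paths`, computed by a large complete-data fit), and all
  recovery claims for the missing-data machinery are made against that
  estimand: multiple imputation can only be expected to recover what
  complete data identify. Recovery at n = 900 with 30% MAR missingness, M =
  20 and 50 replicate seeds reproduces the estimand paths well within
  Monte-Carlo error.
* **Missingness.** MCAR masks each target cell independently at its rate.
  MAR masks with probability expit(α_v + w), where w combines the
  standardized wave-0 auxiliary composite (weight 1.0), gender (0.3) and age
  (0.15), and α_v is solved by a bracketing root find so the expected rate
  equals the target; wave-0 auxiliaries and demographics are never masked.
  Because the MAR driver is always observed and enters the imputation model,
  the default scenario is one in which MI is correctly specified — by
  design, so that the machinery is testable. Default rates are the reported
  28–38% per variable.
* **Items.** `generate_items` produces parallel items whose common
  correlation solves the Spearman–Brown relation for the target alpha, with
  the error variance reduced by 1/12 to compensate for rounding to the
  Likert grid (without this, recovered alpha for short coarse scales
  undershoots by ~0.05). Items are rounded and clipped last; reverse items
  are flipped so raw item matrices look like real questionnaire data.
* **Seeds.** One master seed; each stage (exogenous draw, demographics,
  structural noise, missingness, items) consumes a deterministically derived
  child stream, so any stage is reproducible in isolation and identical
  seeds give bit-identical panels.

What the generator does **not** emulate: wave-clustered nonresponse (the
study's complete-case count implies students missed whole waves, whereas the
generator masks per variable independently — so generated complete-case
counts are much lower at the same marginal rates), skewed/ordinal latent
distributions, and MNAR mechanisms. Passing tests therefore certify the
estimation machinery under a clean MAR Gaussian world, not robustness to
those departures.

## Imputation

Joint multivariate-normal data augmentation over the nine analysis variables,
four auxiliaries, age, gender, and dummy-coded generation (17 columns):

* **I-step.** Rows are grouped by missingness pattern and patterns by number
  of missing cells; with precision matrix P = Σ⁻¹ the conditional law of the
  missing block is N(μ_m − P_mm⁻¹ P_mo (y_o − μ_o), P_mm⁻¹), and the P_mo
  products for every row at once reduce to a single matrix product with the
  observed residuals (missing coordinates zeroed). All factorizations and
  solves are batched per pattern group, which is what makes full-length
  chains affordable in pure numpy.
* **P-step.** Under the Jeffreys prior, Σ | data ~ inverse-Wishart(n−1, S)
  and μ | Σ ~ N(ȳ, Σ/n); the Wishart draw uses scipy. A proper posterior
  needs n − 1 ≥ p (17 variables ⇒ n ≥ 18); smaller tables are rejected with
  a clear error.
* **Chains and the gate.** ≥2 chains start from overdispersed states
  (jittered means, inflated/deflated diagonal covariances). Means and
  variances over the second half of the burn-in feed the PSRF,
  √(((L−1)/L·W + B/L)/W); imputations are drawn only when max PSRF < 1.05,
  from a single chain at spacing ⌊post/M⌋, unless the caller explicitly
  overrides (the override is logged). Note two properties of this statistic:
  bit-identical chains give √((L−1)/L), i.e. 1 only asymptotically in L; and
  at the short retained windows used in reduced-scale simulations the PSRF
  is noisy around the 1.05 gate, which is why reduced-scale test runs use
  the logged override while the full-scale defaults (burn-in 5000, retained
  2500) sit comfortably below the gate. With nothing missing the gate is
  vacuous and MI degenerates to M copies of the input.
* **Materialization.** Observed cells are never altered. Imputed continuous
  values are clipped to their scale bounds but never rounded to the Likert
  grid (scale scores are quasi-continuous item means); gender is rounded to
  {0, 1} and generation mapped to the nearest category from its dummies.
  Near-singular covariance draws are ridge-regularized (ε = 1e−6, counted
  and logged).
* **Alternative engines.** A fully-conditional-specification imputer
  (per-variable normal regression with posterior draws, 5 sweeps) and a
  complete-case baseline exist for the sensitivity grid only; joint DA is
  the default engine.

## Pooling and bootstrap inference

Rubin's rules per coefficient: Q̄ (mean), W̄ (mean squared SE), B
(between-imputation variance, ddof 1), T = W̄ + (1 + 1/M)B, with
Barnard–Rubin degrees of freedom against the complete-data residual df
(ν_obs = (ν+1)/(ν+3)·ν·(1−λ), harmonically combined with (M−1)/λ²), t = Q̄/√T
and a two-sided t-distribution p-value.

**Imputation-then-bootstrap (default):** B case resamples (rows with
replacement, size n) from each of the M completed datasets, fit by a
vectorized batched normal-equations solver (verified against statsmodels to
1e−10); all M·B draws pooled per effect. Replicates whose Gram matrix has
condition number above 1e10 are treated as rank-deficient and redrawn
(counted, capped at 25 rounds). **Bootstrap-then-imputation:** B resamples of
the incomplete table, each imputed m_per_boot times (default 2) with a short
single chain (default burn-in 500 — full-length chains per replicate would be
computationally disproportionate); the draw is the mean over the replicate's
imputations, and replicates in which some variable loses all observed values
are redrawn. Point estimates in both orders are means over imputations of
per-imputation products, never bootstrap functionals.

Percentile intervals use the empirical inverse-CDF convention: the bound at
level q is the ⌈qn⌉-th order statistic, computed directly with an epsilon
guard so the convention is stable when q·n lands on an integer. Conventions
differ only in the 4th decimal at the default draw counts, but the choice is
fixed and documented. An interval is "significant" when it excludes zero.

Under the null (a = 0) the pooled 95% percentile interval for the
private-regard indirect effect excludes zero at the nominal rate (measured at
5.5% over 200 reduced-scale replicates, within two binomial SEs of 5%).

## Problem sizes used by the test suite and acceptance script

Full-scale defaults (burn-in 5000, 10,000 post-burn iterations, M = 100,
B = 1000) are the package defaults and are exercised once for the exact
M×B = 100,000 draw-count check at n = 50. Simulation studies run at reduced
scale chosen as a deliberate design point: parameter recovery at n = 900,
30% MAR, M = 20, burn-in 200, 50 replicate seeds; null calibration at
n = 250, 25% MCAR, M = 5, B = 120, 200 replicates; the acceptance script's
end-to-end study at n = 891, M = 20, B = 200, burn-in 500. MVN data
augmentation mixes in tens of iterations at these dimensions, so short
burn-ins are adequate for simulation purposes while the defaults retain the
conservative full-length settings.

## Numerical choices and degenerate inputs

* Ridge ε = 1e−6 on near-singular covariance factorizations (logged).
* Gram-condition threshold 1e10 for declaring a bootstrap replicate
  rank-deficient (LAPACK will "solve" numerically singular systems silently,
  so an explicit condition check is required).
* Intercept search for MAR calibration: Brent bracketing on [−20, 20].
* Clipped-normal moment calibration: hybrid-Powell root find on (μ, log σ);
  infeasible targets (SD too large for the bounds) are rejected.
* Fully observed input: imputation returns M identical copies; B = 0 in
  pooling; bootstrap orders coincide with the ordinary case bootstrap.
* Zero residual noise in the mediator equations makes the outcome design
  exactly collinear (mediators deterministic in X, U); this is detected and
  reported as rank deficiency rather than silently fit.

## Limitations

Estimation assumes the five-equation linear system; no latent-variable (SEM)
measurement model, no moderated mediation, no causal sensitivity analysis.
The imputation model is joint-normal over score-level variables — ordinal
item-level imputation and multilevel structure are out of scope, and
equivalence with any specific proprietary imputation engine is not claimed,
only the same model class (MVN data augmentation with auxiliaries). BCa,
studentized and Monte-Carlo interval flavors are not implemented. The
generator's limitations are listed above; in particular, results under
wave-clustered or MNAR nonresponse are untested.
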