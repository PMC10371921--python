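# panelmediate

Longitudinal **parallel multiple mediation** with missing data: multiple
imputation by joint-normal data augmentation, a five-equation OLS path system,
Rubin's-rules pooling, and nested percentile-bootstrap inference on specific
and total indirect effects — plus a synthetic two-wave panel generator with
known true paths so the whole chain is testable against ground truth.

## The problem

A two-wave school survey asks whether early adolescents' perception of an
exclusionary immigration law (a 1–9 scale, X, measured at wave 1) affects
their global self-esteem seven months later (Y, wave 2) *through* three
dimensions of ethnic identity measured at wave 2 — ethnic centrality (M₁),
ethnic private regard (M₂) and ethnic public regard (M₃) — holding the wave-1
measures of all four repeated constructs (U₁…U₄) constant. Roughly a third of
every analysis variable is missing; wave-0 scores of the same constructs serve
as auxiliary variables for imputation.

The path system (all equations OLS, classical SEs):

```
M̂ⱼ = i_Mⱼ + aⱼ X + u₁U₁ + u₂U₂ + u₃U₃ + u₄U₄          j = 1, 2, 3
Ŷ  = i_Y + c′X + b₁M₁ + b₂M₂ + b₃M₃ + u₁U₁ + … + u₄U₄
Ŷ  = c₀ + c₁X + c₂U₁ + … + c₅U₄                        (total effect)
```

Specific indirect effects are the products `aⱼ·bⱼ`; the total indirect effect
is their sum; and for OLS on a common dataset with matching covariate sets the
decomposition `c₁ = c′ + Σ aⱼbⱼ` holds exactly.

Inference pipeline, mirroring the study design:

1. **Multiple imputation** — joint multivariate-normal data augmentation
   (I-step/P-step Gibbs, Jeffreys normal–inverse-Wishart prior) over the nine
   analysis variables, four auxiliaries and dummy-coded demographics; ≥2
   chains from overdispersed starts gated by the Gelman–Rubin PSRF < 1.05;
   default burn-in 5000, then M = 100 datasets saved at equal spacing over
   10,000 iterations.
2. **Estimation** — the five equations fit on each completed dataset; pooled
   by Rubin's rules with Barnard–Rubin degrees of freedom.
3. **Bootstrap** — B = 1000 case resamples from each of the M = 100 completed
   datasets; all M×B = 100,000 draws pooled per indirect effect into 95%
   percentile intervals (imputation-then-bootstrap). The reversed nesting
   (bootstrap-then-imputation, short chains inside each replicate) is
   available as an alternative, and a sensitivity grid re-runs the analysis
   over imputation engines × bootstrap orders × covariate handling.

## Worked example

```python
from dataclasses import replace
from panelmediate import (
    default_config, generate_panel, impose_missingness,
    ImputationConfig, multiply_impute, fit_equations,
    rubin_pool, pool_indirect_effects,
    imputation_then_bootstrap, percentile_ci,
)

# a synthetic study at the default conditions: n = 891, MAR missingness
# at the reported 28-38% rates, true paths at the published magnitudes
cfg = default_config(n=891, seed=5)
panel = impose_missingness(generate_panel(replace(cfg, missing_rates={})), cfg)

imp = ImputationConfig(burn_in=300, post_burn_iterations=100,
                       n_imputations=20, seed=1)
imputations = multiply_impute(panel, imp, force=True)   # short demo chains
fits = [fit_equations(t.to_frame()) for t in imputations.completed_tables]

pooled = rubin_pool(fits)
print(pooled.coefficient("m2", "x_t1")[["estimate", "se", "df"]].round(4))
# estimate    0.0247
# se          0.0121
# df         52.9933

print({k: round(v, 5) for k, v in pool_indirect_effects(fits).items()
       if k in ("a2b2", "total_indirect", "direct")})
# {'a2b2': 0.00268, 'total_indirect': 0.00314, 'direct': -0.00921}

dist = imputation_then_bootstrap(panel, imp, B=200, seed=2,
                                 imputation_set=imputations)
ci = percentile_ci(dist)["a2b2"]
print(round(ci.lower, 4), round(ci.upper, 4), ci.significant)
# 0.0001 0.0069 True
```

The pooled private-regard path (`a2 ≈ 0.025`, one extra scale point of
perceived policy impact predicts ~0.025 points higher private regard seven
months later, net of wave-1 levels), its outcome path (`b2 ≈ 0.12`) and their
product (`a2b2 ≈ 0.003`, with a 95% percentile interval from the pooled
bootstrap draws) are the quantities of interest; the fractional pooled df
(~53) reflects the Barnard–Rubin adjustment under ~30–38% missingness.

A command-line interface wraps the same steps:

```bash
panelmediate simulate --n 891 --seed 5 --out panel.csv
panelmediate describe --input panel.csv --out-dir results/
panelmediate bootstrap --input panel.csv --order itb \
    --m 20 --b 200 --burn-in 300 --post 100 --force --out results/cis.csv
```

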