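# jointsnp

Joint modelling of SNP effects on a longitudinal biomarker and a
time-to-event trait — the setting of genetic cohort studies in which a
repeatedly measured marker (here fasting plasma glucose, FPG, in mmol/L)
and disease onset (type-2-diabetes diagnosis) are driven by the same latent
subject trajectory, and each SNP may act on both processes.

The package is for biostatisticians and statistical geneticists who want to

* fit the **shared-parameter joint model** per variant,
* use the fast **two-step (TS)** approximation as a genome-scale pre-filter,
* benchmark both against the naive **extended Cox** model with the raw
  biomarker carried forward, and
* run the **simulation studies** (RMSE, bias, variance, power, type-I
  error) that justify the choice between them.

## Model

For individual *i* with biomarker measurements *Y*<sub>ij</sub> at times
*t*<sub>ij</sub>, dosage *Z*<sub>i</sub> ∈ [0, 2] and covariates
*W*<sub>i</sub>:

```
Y_ij = X_ij + ε_ij,              ε_ij ~ N(0, σ²)
X_ij = θ0_i + θ1_i·t_ij + γ·Z_i + δ'W_i,   (θ0_i, θ1_i) ~ N₂(μ, Σ)
λ_i(t) = λ0(t)·exp(β·X_i(t) + α·Z_i + η'W_i)
```

γ is the per-allele effect on the biomarker, α the direct per-allele
log-hazard effect, and β links the (true, error-free) trajectory to the
hazard. λ0(t) is piecewise constant with two interior knots (placed at the
event-time tertiles). The observed-data likelihood integrates the shared
random effects out by adaptive Gauss–Hermite quadrature; maximisation is
quasi-Newton with an analytic score. Because the biomarker stops being
measured at diagnosis (treatment alters it), it is an *endogenous*
covariate: the joint likelihood handles this correctly, while the extended
Cox model does not — quantifying that gap is what the simulation engine is
for.

Estimators provided, statsmodels-style (`Model(...).fit()` → results object
with `params`/`estimates`, `bse`, `llf`, `summary()`):

| class | estimator |
|---|---|
| `JointModel` | full joint likelihood ("JM"), Wald + LRT tests |
| `TwoStepModel` | mixed-model fit, empirical-Bayes trajectory plugged into the Cox partial likelihood |
| `LongitudinalMixedModel` | random intercept/slope mixed model alone (ML) |
| `CoxTimeVaryingModel` / `CoxFunctionalModel` | Breslow partial likelihood on episode or exact affine-trajectory covariates |

## Worked example

Simulate one cohort under the reference parameter set (4,352 individuals,
four 3-yearly visits over 9 years, 3.84% incidence, effect-allele frequency
0.244) and fit the two-step estimator:

```python
from jointsnp import (table1_defaults, table1_scenario, calibrate_lambda,
                      simulate_cohort, fit_two_step)

params = table1_defaults()
params = params.with_lambda(calibrate_lambda(params, 0.0384))
sim = simulate_cohort(table1_scenario(base_seed=42), params, replicate=0)
res = fit_two_step(sim.cohort, genotype=sim.truth["z"].to_numpy())
print(res.summary())
```

```
Two-step estimator (LME trajectory plug-in Cox)
converged: True
parameter         estimate          se  stage
gamma              0.02685     0.00997  stage1
beta               2.77091     0.24051  stage2
alpha              0.27116     0.12019  stage2
```

The stage-1 genotype effect (0.027 mmol/L per allele, true value 0.0229)
comes from the mixed model; the stage-2 trajectory–hazard link (2.77, true
value 3.17 — note the plug-in attenuation the joint model avoids) and the
direct genotype hazard effect (0.27, true 0.265) come from the partial
likelihood on the empirical-Bayes trajectories. `JointModel(...).fit()` on
the same cohort removes most of the attenuation at ~100× the cost.

A command-line interface mirrors the library
(`jointsnp simulate|calibrate|fit-lme|fit-ts|fit-jm|evaluate|scan`); run
`jointsnp --help`.

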