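# Methods

## Model and estimators

The package targets the standard shared-parameter joint model for a
longitudinal biomarker and a time-to-event outcome with per-variant genetic
effects. Conditional on the subject random effects b_i = (θ0_i, θ1_i) the
two processes are independent:

* longitudinal: Y_ij | b_i ~ N(θ0_i + θ1_i t_ij + γZ_i + δ'W_i, σ²),
  with b_i ~ N₂(μ, Σ);
* survival: hazard λ_i(t) = λ0(t) exp(βX_i(t) + αZ_i + η'W_i), where
  X_i(t) is the error-free affine trajectory (including the fixed genotype
  and covariate shifts).

Because X_i is affine in t and λ0 is piecewise constant, the conditional
cumulative hazard is a closed-form sum of ∫exp(βθ1_i s) ds terms over the
baseline pieces; only the 2-D integral over b_i is numerical.

Four estimators share this data model:

1. **JM** — maximises the integrated likelihood. The b_i integral uses
   Gauss–Hermite quadrature (default 5 points/dimension, 25 nodes) made
   adaptive by recentring at each subject's posterior mode of b_i and
   rescaling by the posterior curvature; the subject log-joint is strictly
   concave in b_i, so the vectorised 2-D Newton mode search is safe.
   Optimisation is L-BFGS on an unconstrained scale (log-Cholesky Σ, log σ,
   log rates) with the *analytic* gradient — the posterior-weighted
   complete-data score — and up to three node-refresh sweeps; convergence
   when a sweep changes the log-likelihood by < 1e-8 (relative) or all
   parameters by < 1e-6. Starting values come from the two-step fit.
   Standard errors are the inverse central-difference observed information,
   delta-mapped to the natural scale. An EM algorithm would also satisfy
   the contract; direct maximisation with an exact gradient was chosen
   because no closed-form M-step exists for β and the gradient makes
   quasi-Newton both faster and simpler to verify (it is checked against
   finite differences in the tests).
2. **TS** — the mixed model is fit first (ML); the empirical-Bayes
   trajectory X*_i(t) = θ̂0_i + θ̂1_i t + γ̂Z_i (+ δ̂'W_i) is then plugged
   into the Cox partial likelihood with Z_i kept as a separate covariate.
   Posterior means are used for b̂_i (they equal the modes under
   Gaussianity). Stage-2 standard errors are deliberately naive — no
   propagation of stage-1 uncertainty — because that approximation *is*
   the method under study.
3. **Extended Cox (LOCF)** — the raw measured biomarker carried forward on
   (t_j, t_{j+1}]; the naive standard practice whose measurement-error and
   endogeneity bias the simulation study quantifies.
4. **LME alone** — the longitudinal sub-model, also used for γ inference.

The mixed model is estimated by profiled ML: fixed effects by GLS at each
variance-parameter value, the 4-parameter profile likelihood (log-Cholesky
Σ, log σ) by L-BFGS with a Nelder-Mead polish. Individuals sharing a
measurement-time pattern share one marginal covariance, and the data enter
only through per-block sufficient statistics, so one likelihood evaluation
is O(#patterns) — on a common visit schedule that is m+1 blocks regardless
of n. ML (not REML) keeps the TS and JM log-likelihoods comparable and
LRTs valid. The model is fit to the dropout-truncated records as-is.

The Cox engine maximises the Breslow partial likelihood by Newton–Raphson
with step-halving; risk sets use half-open (start, stop] episodes. For
affine trajectories the covariate is evaluated *exactly* at each event time
(sorting subjects by follow-up makes each risk set a prefix), avoiding any
step discretisation. Ties are Breslow (simulated event times are
continuous); monotone likelihoods (separation) are detected by a coefficient
diverging past 15 on these data scales and flagged, as are zero-information
covariates (coefficient 0, infinite SE).

## Hypothesis tests

Wald tests are two-sided normal (estimate/SE). The SNP likelihood-ratio
test compares the full joint model against the nested fit with α = 0 (SNP
removed from the survival sub-model only), 1 df; if the reduced fit ever
beats the full one the full model is re-polished from the reduced optimum
before the statistic is formed.

## Synthetic-data engine

The generator emulates a diabetes cohort: n individuals followed 9 years
with m evenly spaced visits on [0, 9] (default m = 4, i.e. 3-yearly),
Hardy–Weinberg genotypes Z_i ~ Binomial(2, f), bivariate-normal random
intercept/slope, Gaussian measurement error, constant baseline hazard, and

* event times by exact inverse-transform sampling: H_i(T) = −log(1−u)
  solved in closed form; when βθ1_i < 0 the cumulative hazard is bounded
  and the draw may be +∞ (no event ever) — handled, censored at 9 years;
* administrative censoring at the horizon; no random loss to follow-up;
* event-driven dropout: measurements strictly after min(T_i, 9) are
  removed (the baseline visit is always retained);
* λ0 calibrated to a target 9-year event proportion d by Brent root
  finding on a deterministic quadrature (40-point Gauss–Hermite over the
  random-effect law × the exact dosage distribution), tolerance 1e-4 —
  deterministic rather than stochastic search, for reproducibility.

Default parameter values (`table1_defaults`) correspond to a strong
TCF7L2-type locus: μ = (4.55, 0.0108), Σ = [[0.143, −0.00109],
[−0.00109, 6.8e-4]], σ = 0.305 mmol/L, γ = 0.0229, α = 0.265, β = 3.17,
f = 0.244, d = 0.0384, n = 4,352. The scenario grid crosses
m ∈ {2,3,4,5}, n ∈ {500, 1000, 2500, 5000, 10000}, f ∈ {0.05, 0.1, 0.25,
0.5}, d ∈ {0.025, 0.05, 0.1} — 240 cells; per-replicate seed streams are
derived from (base seed, cell index, replicate), so all estimators see
identical data within a replicate (paired comparisons).

What the generator does **not** emulate: covariate effects (δ, η — fitting
supports them, the simulations omit them), SNP×time interaction, visit-time
jitter or missed visits, non-Gaussian biomarker error, random loss to
follow-up, linkage between variants. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to those real-data features.

## Evaluation harness

Per scenario × method × parameter (γ, α, β): RMSE about the generative
truth with its exact decomposition rmse² = bias² + variance (variance taken
about the replicate mean), Wald rejection rate at a nominal level, and the
convergence-failure rate. Non-converged replicates are excluded from the
moment summaries but always reported through the failure rate. The type-I
error null sets γ = α = 0 with β and all nuisance parameters at the
reference values; power is rejection under the reference alternatives.

## Variant QC

Call rate, minor allele frequency (on non-missing calls) and an exact
conditional Hardy–Weinberg test (Wigginton-style: condition on allele
counts, sum probabilities of heterozygote counts no more probable than
observed; the standard, not mid-p, variant). Default thresholds 0.95 /
0.05 / 1e-5. Fractional dosages are rounded to hard calls for the HWE test
only; association fits use raw dosage. In scans, sporadically missing
dosages are mean-imputed (QC guarantees ≥95% call rate first).

## Numerical choices and degenerate inputs

* Quadrature nodes are held fixed within each L-BFGS sweep so the
  objective is smooth; at β = 0 the adaptive rule integrates the Gaussian
  posterior exactly, which is the factorisation oracle the tests lean on.
* Piece integrals ∫sᵏ e^{cs} ds switch to first-order series below
  |c| < 1e-7 to avoid cancellation.
* Baseline knots default to event-time tertiles; tied or degenerate
  tertiles fall back to (horizon/3, 2·horizon/3). Fewer than 3 events is
  an error; zero events makes the survival parameters unidentifiable and
  `JointModel` refuses the cohort.
* The 33%-tertile knot choice, 5-point rule, and ML-vs-REML were open
  design decisions; each is configurable (`BaselineSpec`,
  `QuadratureSpec`, the LME is ML-only by design).
* HWE p-values accumulate probabilities with a 1e-12 relative tie
  tolerance so exact ties with the observed configuration count as "as
  extreme".

## Problem sizes used in the checked runs

The test suite and `scripts/acceptance.py` run at desk scale, chosen to
keep the full suite in the tens of minutes on one core while leaving every
stochastic acceptance band at three Monte-Carlo SEs: 20 cohorts of
n = 4,352 for the incidence check; 50 mixed-model fits at n = 5,000 for γ
recovery; 20 oracle Cox fits at n = 10,000 for (β, α) recovery; 30
replicates at n = 350 for type-I error; 12 paired replicates per cell over
n ∈ {250, 500, 2000} at d = 0.1 for the RMSE comparisons (the full grid
with 500 replicates per cell remains available through
`scenario_grid(n_replicates=500)` / the `evaluate` CLI). The RMSE-ordering
and monotonicity conclusions are qualitative and already decisive at these
sizes because the extended-Cox attenuation bias dominates its RMSE.

## Known limitations

* Univariate longitudinal trait, linear time trend, current-value
  association only (no slope or cumulative-effect links), piecewise
  baseline with exactly two knots.
* No left truncation, competing risks, stratification, or Efron ties.
* TS standard errors are intentionally uncorrected (see above); bootstrap
  corrections would change the method under study.
* The joint fit assumes enough events to identify three baseline rates;
  with very low incidence and small n, rate pieces can drift to the
  boundary and the non-convergence flag should be heeded.
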