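# Methods

This note documents the statistical model, the synthetic world it is
exercised on, the numerical choices behind the inference engine, and the
limits of what the test suite demonstrates.

## Continuation-ratio coverage model

Coverage of an ordered dose series (first dose, third dose) is modelled as
two conditional binomials per birth cohort: stage 1 is the probability of
receiving at least one dose, `p1`; stage 2 is the probability of
completing at least three doses *given* at least one, `p3c`. Third-dose
coverage is the product `p3 = p1 · p3c`. The decomposition has two
practical consequences: the stage likelihoods are independent binomials
(stage 2 is fitted on `trials = k1`, `successes = k3`, with `k1 = 0` rows
dropped), and the ordering `p3 ≤ p1` holds by construction in every
posterior draw — it is never enforced by a constraint during fitting.

Each stage's cluster-level observation model is

```
k_i ~ Binomial(n_i, logit⁻¹(η_i))
η_i = β₀ + Σ_j α_j · logit(s_ji) + γ_g(i) + u(x_i, t_i) + ε_i
```

* `s_ji` — out-of-fold stacked-generalization predictions (below). The
  weights `α` live on the simplex (`α_j ≥ 0, Σα_j = 1`), so the stacker
  term is a convex combination of child logits; an unconstrained mode is
  available via `GpSpec(constrain_weights_simplex=False)`.
* `γ_g` — a Normal(0, σ²_γ) random effect per level-1 admin unit. At
  desk scale (one country/state) it preserves the hierarchy that a
  multi-country run would express as country effects.
* `u(x, t)` — zero-mean Gaussian process with separable covariance
  `C((x,t),(x',t')) = σ²_s · Matérn_ν(|x−x'| / ℓ) · ρ^|t−t'|`, i.e. the
  Kronecker product of an AR1 kernel in time and an isotropic stationary
  Matérn kernel in space. Smoothness is fixed at ν = 3/2 (closed form,
  once-differentiable realizations); ν ∈ {1/2, 5/2} are supported.
* `ε_i` — Normal(0, σ²_ε) observation-level nugget ("irreducible error").
  It absorbs cluster-level noise that is not spatially structured and is
  **excluded from prediction**: predicted surfaces carry the GP, the group
  effect and the fixed effects only.

### Priors and parameterisation

| parameter | prior | transform used internally |
| --- | --- | --- |
| β₀ | Normal(0, 3²) | — (part of the latent Gaussian) |
| σ_s, σ_ε, σ_γ | half-Normal(0, 1) | log |
| ρ | Uniform(−0.99, 0.99) | atanh |
| ℓ (spatial range) | log-Normal centred on the supplied value (default: ¼ of the domain diameter), log-sd 0.75 | log |
| α | softmax of J−1 free logits with Normal(0, 1.5²) priors (≈ flat over the simplex interior) | softmax |

Priors are weakly informative and configurable through `GpSpec`. The
supplied `GpSpec` values double as prior centres and optimizer starting
points; any hyperparameter can be frozen via `fixed=(...)`, and a variance
fixed at zero removes its term from the model entirely (used heavily in
degenerate-contract tests).

### Inference: nested Laplace with hyperparameter mixing

The engine is a nested-Laplace scheme in the INLA family, written for this
package (any engine satisfying the recovery and oracle contracts would
do):

1. **Collapse the latent field to the observations.** For fixed
   hyperparameters θ, every Gaussian term (β₀, γ, u at the data support,
   ε) marginalizes into one n×n prior covariance for η:
   `C = σ²_β·11ᵀ + σ²_γ·ZZᵀ + K_st + σ²_ε·I`, with prior mean
   `m = Σ_j α_j logit(s_j)`. Only the binomial likelihood is non-Gaussian.
2. **Laplace over η.** The mode of `log p(y|η) − ½(η−m)ᵀC⁻¹(η−m)` is found
   by the standard stabilized Newton iteration for GP models with
   non-Gaussian likelihoods (factorizing `B = I + W^½ C W^½`), giving an
   analytic approximate marginal likelihood `log q(y|θ)`.
3. **Laplace over θ.** `log q(y|θ) + log prior(θ)` is maximized
   (Nelder–Mead on transformed scales, ≤ 300 evaluations), the Hessian
   estimated by central finite differences (step 0.08, jittered to
   positive definiteness), and `n_theta` points (default 25) sampled from
   the resulting Gaussian.
4. **Mixture sampling.** The `n_draws` posterior draws are split evenly
   across the θ points; within each point, η is drawn from its Gaussian
   approximation and the structured parameters (β₀, γ, u at the data
   support) are recovered by exact linear-Gaussian conditioning on the η
   draw — the identity `C = FΣ_bFᵀ + σ²_ε I` makes this conditioning
   consistent with step 1 by construction.
5. **Prediction.** Per θ point, unconditional GP draws over the full
   grid×years are generated through the Kronecker factorization
   (`chol(Matérn) ⊗ chol(AR1)`), then conditioned on each draw's support
   values by Matheron's rule (`u* = u_prior + K_*s K_ss⁻¹ (u_s − u_prior,s)`).
   This keeps the per-draw cost at one matrix–vector product.

Reporting hyperparameter uncertainty as a finite mixture over ~25 sampled
θ points (rather than per-draw θ) trades some tail resolution of ρ and ℓ
for an order-of-magnitude speedup; the recovery experiment shows 85–100%
coverage of 95% intervals for β₀ and ρ across seeds, and pixel-level 95%
predictive intervals covering the simulated truth at ≈ 92–94%, inside the
nominal-coverage band the suite requires.

Numerical guards: probabilities are clipped to [1e−4, 1−1e−4] before any
logit; covariance diagonals get 1e−8 jitter before factorization; joint
GP dimensions beyond 20,000 are refused with an instruction to coarsen
the grid (dense Kronecker algebra is the intended regime — desk-scale
grids of ≤ ~25×25 pixels × ≤ 6 years).

## Covariate selection and stacking

**VIF pruning.** `VIF_j = 1/(1−R²_j)` from an OLS regression of covariate
j on the others (with intercept), computed at the observation sites (the
multicollinearity that matters for fitting is at the data); covariates are
removed one at a time, highest VIF first, until all VIFs ≤ 5 (threshold
configurable). Ties keep the earliest column. Perfect collinearity is
reported as an infinite sentinel, never a crash.

**Child learners.** Three children per stage, all consuming the selected
covariates and producing probabilities, binomially weighted by expanding
each observation into success/failure rows with trial-count weights:

* *additive smooth*: per-covariate cubic B-spline bases (5 knots) +
  ridge-logistic fit — an additive smooth logistic model;
* *L1-penalized logistic*: lasso path over 8 C values by internal 3-fold
  CV (liblinear, with a large intercept scaling so the intercept is
  effectively unpenalized);
* *boosted trees*: gradient boosting (logistic objective, 100 rounds,
  depth 3, learning rate 0.05, `min_child_weight` 50 and split gain
  threshold 1 in children-equivalent units — tuned so pure noise yields no
  splits at desk scale).

Folds are spatially stratified: LGAs are shuffled and dealt round-robin so
same-LGA clusters always share a fold (falling back to random cluster
folds, with a warning, when there are fewer LGAs than folds). Out-of-fold
predictions never touch the held-out fold's outcomes — a property the
suite checks bitwise. A child that fails to fit degrades to the
observation-weighted mean rate with a warning rather than aborting the
stack.

## Calibration and aggregation

Raking solves one logit-scale shift δ per dose-year so that the
population-weighted mean of the **raked** posterior-mean surface equals
the national target: the root of
`Σ_{d,s} (w_s/D)·logit⁻¹(logit(p_{d,s}) + δ) = target` (Brent's method on
[−30, 30], residual < 1e−10). Solving over draws jointly — not on the
pre-raking mean surface — matters because the sigmoid does not commute
with draw-averaging; it is what makes the calibration exact. A per-draw
mode (one δ per draw) is available. Doses are raked independently and the
third-dose draws then capped at the first-dose draws; cap counts are
logged and reported. When the model's relative dose levels disagree with
the national series the cap can bite on a noticeable share of cells
(~9% in the default synthetic run) — joint raking of the two doses would
avoid this and is noted as an alternative, not implemented.

Aggregation is a population-weighted mean over a unit's pixels, per draw,
so state-level draws are exactly the population-weighted means of their
LGAs' draws (conserved to 1e−12); uncertainty intervals are 2.5/97.5
percentiles across draws with linear interpolation. Zero-population units
are flagged missing and excluded from parent weights. "Share of units
increasing" uses strict inequality — ties do not count as increases.

## The synthetic world

The generator produces the statistical structure the analysis assumes,
with defaults chosen once to mirror a conflict-affected state of the kind
the audit targets (a "Borno-like" region):

* 27 LGAs in 1 state on a 15×15–27×27 grid of 5 km pixels; rectangular-ish
  contiguous tiles;
* smooth standardized Matérn-3/2 covariate fields (range ≈ 35% of the
  domain), one engineered collinear pair (r = 0.9) to give the VIF stage
  work; covariates are time-invariant, replicated across years;
* truth surfaces from the model's own generative process: logit-linear in
  two informative covariates (stage-1 intercept −0.2, stage-2 0.3) plus an
  AR1(0.7) ⊗ Matérn GP (variances 0.3 / 0.2) — modest coverage rising over
  time, consistent with a low-coverage, improving region;
* population: mixture of Gaussian urban kernels (3 centres, 70% of mass)
  over a uniform floor, total 500,000; an alternative raster (different
  centres) supports the population-sensitivity comparison;
* conflict: Poisson(10) events per affected-LGA-year, Poisson(7)
  fatalities, 21 affected LGAs; events uniform within their LGA;
* survey: 150–200 clusters placed proportional to population, 20 children
  per cluster, ages uniform on 12–59 months, cohort year =
  survey_year − floor(age/12); the survey is fielded the year after the
  modelled span so all cohorts fall inside it; conflict-affected LGAs are
  dropped whole with probability 1. The most populous LGA (the state
  capital analogue) is kept accessible, so the default run leaves ~3–6
  LGAs sampled holding ~18–25% of the population — the qualitative
  pattern of a survey whose field teams are locked out of most of a state
  but can still work the capital.

What the generator does **not** emulate: displacement and population
movement, card-versus-recall measurement error, age heaping, cluster-size
variation, within-LGA partial dropout, and any covariate-conflict
feedback. Passing tests therefore demonstrate internal correctness of the
estimation machinery under the model's own assumptions — not robustness
to the measurement pathologies of real conflict-zone surveys.

## Validation

`geovax.validation.recovery_experiment` simulates from the generative
model (known β₀ = −0.4, ρ = 0.7, GP variance 0.5, nugget 0.1; 15×15 grid,
4 years, 150 clusters of 20, 250 draws), refits, and scores (a) 95%
credible-interval coverage of β₀ and ρ across 20 seeded replicates and
(b) pooled pixel-level 95% predictive-interval coverage of the truth
surface. Prior centres are deliberately offset from the generating values
(spatial variance 0.3 vs 0.5, ρ 0.5 vs 0.7) so recovery is not an
artifact of prior centring.

## Reproducibility

Every simulator and the fitting engine are deterministic given
(parameters, seed). The pipeline expands its single seed into per-stage
seeds via `SeedSequence([seed, stage_index])`, records sha256 digests of
every persisted artifact in a run manifest, and reruns reproduce digests
bit-for-bit. Tests and the acceptance script run the chain at desk-scale
problem sizes (12×12–15×15 grids, 80–150 clusters, 100–250 draws), the
sizes at which the dense Kronecker algebra is comfortably interactive;
the configuration defaults keep 1000 draws for production-style runs.

## Known limitations

* Laplace approximations can understate skewness in hyperparameter
  posteriors; ρ intervals are approximately calibrated (85–100% empirical
  coverage at nominal 95%) rather than exact.
* The finite θ-mixture (default 25 points) limits resolution of extreme
  posterior quantiles of hyperparameters.
* Raking treats the national series as exact (no national uncertainty) and
  doses as independent, with post-hoc capping.
* Dense covariance algebra bounds the prediction support to ~20,000
  pixel-years; larger domains need a sparse/inducing-point engine.
* Polygon-referenced (non-GPS) observations are out of scope; observations
  must carry a pixel.
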