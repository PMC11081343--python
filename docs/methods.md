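# Methods

## The model

`quiltsurv` fits a joint Bayesian model for inpatient episodes consisting of
two linked regressions:

**Outcome (wait time).** The time `T_n` from discharge to the next unplanned
acute admission or death follows a piecewise exponential model (PEM): the
hazard is constant within intervals delimited by breakpoints at 7, 28 and 63
days (one, four and nine weeks after discharge; four intervals, the last
open-ended). Within interval `i` the log hazard for episode `n` is linear,

```
log λ_ni = α_i(κ_n) + β_i(κ_n)'x_n + γ_i(κ_n)'I_n ,
```

with an all-binary design `x_n` and a 10-entry treatment covariate vector
`I_n`. An event contributes `log λ(T) − Σ_i λ_i Δ_i(T)` to the likelihood
and a censored episode contributes the cumulative-hazard term only, where
`Δ_i(T)` is the overlap of `[0, T)` with interval `i`. Intervals are
left-closed/right-open; an event exactly at a breakpoint uses the later
interval's hazard. Administrative censoring at the end of the observation
window (default 90 days) is treated like any other censoring; readmission
and death form a single composite event (no competing-risks decomposition).
Recorded same-day events are floored to T = 0.5 days at data loading
(configurable via `PEMConfig.min_wait_days`), since the density requires
T > 0.

**Treatment assignment (discharge placement).** Placement
`I_n ∈ {0..5}` is ordered by care acuity (home → home health → skilled
nursing → intermediate care → long-term care → other inpatient) and modeled
by a proportional-odds regression

```
Pr(I_n ≥ k | x_n) = σ(ξ(κ_n)'x_n − c_k(κ_n)),   c_1 < … < c_5 .
```

Cutpoints are parameterized as a free first cutpoint plus cumulative
softplus increments, so the ordering holds by construction. The five
exceedance probabilities, concatenated with the observed indicators
`1{I_n ≥ k}`, form the treatment covariate vector `I_n` of the outcome
model. Including the assignment probabilities as outcome covariates absorbs
the component of placement selection that is predictable from the observed
features — the confounding-by-indication adjustment. The exceedance entries
are recomputed per posterior draw inside the joint density (not frozen from
a first-stage fit), so assignment and outcome are inferred jointly.

## The quilt: parameter decomposition over a cohort lattice

Every parameter above (α, β, γ, the cutpoints, ξ) varies over a discrete
lattice of cohorts — in the intended application, a bucketized
low-dimensional embedding of claims history crossed with discrete admission
attributes. A cohort-specific value is represented additively,

```
θ(κ) = θ(*,…,*) + Σ_d θ(κ_d) + Σ_{d<e} θ(κ_d, κ_e) + … ,
```

truncated at a maximum interaction order (default 2). Sparse cells thus
partially pool toward related lower-order terms. No sum-to-zero constraints
are imposed; identification is by shrinkage alone:

- intercept-like decompositions (α, raw cutpoints) carry zero-mean normal
  priors whose scale is multiplied by `order_scale^order` (default 1/2 per
  order);
- slope decompositions (β, γ, ξ) carry non-centered horseshoe priors
  (coefficient = raw·local·global with half-Cauchy local/global scales),
  again with the geometric per-order multiplier on the implied scale.

Default base scales: 2.0 for intercept-like parameters, 1.0 for slopes —
weakly informative on the log-hazard-ratio scale where effects above ~2 are
implausible for single binary predictors.

### Treatment-effect constraint

The five `1{I≥k}` coefficients of γ are constrained non-positive (more
acute placement never increases the hazard) through a temperature-scaled
smooth hinge `−s·softplus(−g/s)` applied to the materialized coefficient,
with `s = 0.1` by default. The temperature matters: at `s = 1` (plain
negative softplus) a coefficient whose raw value is shrunk to zero maps to
a spurious effect of −log 2 per placement step, so shrinkage itself would
assert a material treatment benefit. At `s = 0.1` the shrunk state implies
an effect of −0.07 (practically null), the map is near-identity for
negative effects, and its gradient at zero is 1/2. The standalone
`constrain_treatment_effects` helper defaults to `s = 1`.

The effect of placement `k` versus discharge home reported by
`treatment_effect_table` is the cumulative sum `Σ_{j≤k} γ_ind,j`, because
the indicator covariates are nested.

## Featurization

Raw count features are expanded into binary columns `1{x ≥ cutoff}` with
cutoffs at per-feature empirical quantiles. The lower (type-1) quantile
definition is used — exactly reproducible from the sorted sample with no
interpolation. Duplicate cutoffs are eliminated, as are cutoffs at or below
the feature minimum (their columns would be constant); features left with
no cutoff are dropped. The default grid is the deciles plus 0.95 and 0.99,
probing the heavy right tail typical of claims counts.

For the history block, a sparse nonnegative linear factorization
(L1-penalized NMF) projects the counts to a low-dimensional embedding
(default 5 dimensions, ordered by explained variance); new data are
projected linearly through the pseudo-inverse of the fitted factor matrix.
Thresholding each dimension at its training median yields `2^latent_dim`
history groups (dimension 0 is the least significant bit of the group
label); crossing these with other discrete attributes gives the lattice.
Whether to take medians from the training split or all data is an
application choice; the implementation computes them from whatever matrix
it is fitted on.

## Inference

Minibatch mean-field ADVI: a fully factorized Gaussian on the unconstrained
latents (softplus transforms for positive quantities, the hinge above for
the constrained block, with log-Jacobians included in the density). The
optimizer schedule is: Adam at initial learning rate 0.0015 inside a
lookahead wrapper (sync period 6, interpolation 0.5), batch size 10⁴ capped
at n, 8 Monte-Carlo samples per step drawn as antithetic pairs (ε, −ε) to
cut gradient noise, a 10% learning-rate decay on every epoch whose mean
loss fails to improve on the best so far, and stopping after 5 consecutive
non-improving epochs or 100 epochs. "Improvement" means any decrease of the
epoch-mean loss. The ELBO gradient needs only ∂log p/∂z (the Gaussian
entropy is analytic), supplied by a small reverse-mode autodiff engine over
float64 numpy arrays written for this package and verified against central
finite differences in the test suite. All density computation is double
precision.

Two initialization details: variational locations start at N(0, 0.01²) and
log-scales at −3, except the zero-order baseline log-hazard, which is
warm-started at the pooled crude events/exposure rate. With the small fixed
learning rate, the number of optimizer steps — epochs × (n / batch size) —
is the travel budget of the fit; intercepts several units from zero are
unreachable from a cold start at desk-scale step counts, while the crude
rate is a one-line consistent estimator of where they live. For the same
reason the bundled analyses use batch sizes of 250–1000 on cohorts of
4,000–20,000 episodes (20–80 steps per epoch), comparable per-epoch step
counts to large-cohort training at batch 10⁴.

## Synthetic data

The generator (`quiltsurv.simulate`) emulates the post-engineering
structure of claims episode data, with full ground truth:

1. a latent health score `h ~ N(0,1)` per episode (higher = sicker);
2. sparse heavy-tailed counts: gamma-mixed Poisson with log-rate
   `a_j + b_j h` (dispersion 0.5 by default);
3. cohort attributes drawn uniformly on the lattice (the default fixture
   uses a 2×2 lattice of two binary admission attributes);
4. placement from the proportional-odds model with linear predictor
   `ξ'x + confounding·h` — latent health tilts placement toward more acute
   care, the confounding mechanism the joint model is built to absorb;
5. wait times drawn from the PEM by inverse-CDF sampling with log-hazard
   `α(κ) + β(κ)'x + Σ_{j≤I} γ_ind,j (+ optionally a direct h term)`,
   censored at 90 days.

The default fixture is n = 20,000 episodes, 10 count features binarized at
their medians, slopes in ±0.6, per-step placement effects
(−0.1, −0.2, −0.25, −0.15, −0.1), confounding weight 1.0, and a baseline
self-calibrated (by bisection on a uniform log-hazard shift) so that ~20%
of episodes have an event within 30 days — the readmission-plus-death rate
typical of the motivating population. In the default fixture the hazard
depends on health only through the observed features, keeping the slope
recovery benchmark unconfounded.

The planted-confounding scenario (`confounding_config`) is harsher:
confounding weight 1.5, heavily loaded features, and a direct (unobserved)
health term of 0.25 in the hazard. Sicker patients both get more acute
placements and are readmitted sooner, so the unadjusted per-placement rate
contrast reports harm where the true effects are protective; the joint
model can remove only the observable component of that bias, which is why
the benchmark asks for a large reduction rather than elimination. The
sparse-signal scenario (`shrinkage_config`, 5 real + 50 null features)
exercises the horseshoe.

What the generator does not emulate: billing-code vocabularies and episode
grouping, time-varying covariates within an episode, competing risks,
informative censoring, cohort-attribute dependence on health, and
calendar-time drift. Passing recovery tests on these cohorts demonstrates
correctness of the machinery under the model's own assumptions, not
robustness to their violation.

## Explanation harness

For a linear-in-coefficients model the exact attribution of a prediction is
`contribution_j = coefficient_j · x_j` plus the cohort/interval base value;
`ground_truth_attribution` reproduces the model output to machine
precision. `kernel_shap` implements regression-based KernelSHAP (Shapley
kernel weights, weighted least squares with the efficiency constraint
imposed exactly, full coalition enumeration when the budget allows,
marginal or exact-match conditional backgrounds). The bundled
twin-feature construction — two perfectly correlated features of which the
model uses one — shows conditional KernelSHAP splitting credit across the
twins while the exact attribution assigns all of it to the used feature,
reproducing the disagreement problem that motivates inherently
interpretable models.

## Numerical choices and limitations

- Ordinal category probabilities are floored at 1e−300 inside the joint
  density before the log; cutpoint increments get a 1e−12 floor to keep
  ordering strict under underflow.
- AUROC is the rank statistic with half-credit ties; AUPRC is average
  precision (step-wise, not trapezoidal); both via scikit-learn, checked
  against an exhaustive pairwise oracle in the tests.
- Mean-field ADVI underestimates posterior variances; reported credible
  intervals are approximate and the package targets point-summary
  interpretation tables. No MCMC backend is provided.
- Epochs drop the final partial minibatch (n mod batch size episodes per
  epoch are unused; batch permutations reshuffle every epoch).
- The decomposition is user-specified, not learned; `max_order` defaults
  to 2, the smallest nontrivial hierarchy.
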