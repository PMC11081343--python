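# quiltsurv

Interpretable piecewise-exponential **quilt** survival regression for
hospital-readmission modeling: a Bayesian survival model whose every
coefficient varies over a lattice of patient cohorts, fit jointly with an
ordinal discharge-placement model that adjusts treatment-effect estimates
for confounding by indication.

The package is aimed at biostatisticians and health-services researchers
who need claims-scale readmission models that are *inherently*
interpretable — every prediction decomposes exactly into named
log-hazard-ratio contributions — rather than post-hoc "explained"
blackboxes. It ships a synthetic claims-like data generator with full
ground truth, so recovery, confounding-adjustment and explainer-benchmark
experiments run end to end without access to restricted claims data.

## The model

For episode `n` with binary design `x_n`, discharge placement
`I_n ∈ {0..5}` ordered by care acuity, and wait time `T_n` to unplanned
readmission or death (right-censored at the observation window):

```
T_n ~ PEM(λ_n)            log λ_ni = α_i(κ_n) + β_i(κ_n)'x_n + γ_i(κ_n)'I_n
I_n ~ Categorical(p_n)    Pr(I_n ≥ k | x_n) = σ(ξ(κ_n)'x_n − c_k(κ_n))
```

- **PEM**: piecewise-exponential hazard over intervals 0–7, 7–28, 28–63,
  63+ days (density `f(t) = λ(t)·exp(−∫₀ᵗ λ)`);
- **I_n** (bold): the 10-entry treatment covariate
  `[Pr(I≥1),…,Pr(I≥5), 1{I≥1},…,1{I≥5}]` — predicted placement
  probabilities plus observed indicators. The probability block carries the
  confounding adjustment; the indicator block holds the causal placement
  effects, constrained non-positive (more acute care never increases the
  hazard);
- **quilt**: every parameter θ ∈ {α, β, γ, c, ξ} is a function of a cohort
  multi-index κ on a discrete lattice (history groups × admission
  attributes), represented by the truncated additive decomposition
  `θ(κ) = θ(*) + Σ_d θ(κ_d) + Σ_{d<e} θ(κ_d,κ_e) + …` with order-graded
  shrinkage priors (normal for intercepts, horseshoe for slopes), so sparse
  cohorts partially pool toward lower-order effects;
- inference: minibatch mean-field ADVI (Adam + lookahead, MC sample size 8,
  learning rate 0.0015 with 10% decay on non-improving epochs, patience 5,
  at most 100 epochs).

See `docs/methods.md` for assumptions, priors, numerical choices and
limitations.

## Worked example

```python
import quiltsurv as q
from quiltsurv.advi import TrainConfig
from quiltsurv.model import QuiltModelConfig
from quiltsurv.pem import PEMConfig
from quiltsurv.evaluate import risk_factor_table, horizon_metrics

cfg = q.fixture_config(seed=0, n=6000)          # claims-like synthetic cohort
df, truth = q.simulate(cfg)
data, cutoffs, names = q.prepare_data(
    df, [f"f{j}" for j in range(10)],
    ["attr_admit_type", "attr_comorbidity"], cfg.lattice,
    quantile_grid=(0.5,))
model, post = q.fit_quilt(
    data, QuiltModelConfig(cfg.lattice, data.X.shape[1], PEMConfig()),
    TrainConfig(batch_size=300, seed=1), column_names=names)

scores = q.risk_scores(model, post, data, horizon=30, n_draws=100, seed=2)
labels = ((df.time <= 30) & (df.event == 1)).astype(int)
auroc, auprc = horizon_metrics(scores, labels)
print(f"30-day AUROC {auroc:.3f}  AUPRC {auprc:.3f}")
table = risk_factor_table(model, post, interval=0, k=5, n_draws=300, seed=3)
print(table.round(3).to_string(index=False))
```

Output (printed by the code above):

```
30-day AUROC 0.675  AUPRC 0.337
predictor interval   mean    sd   lo95   hi95
  f4 >= 2 days 0–7  0.478 0.108  0.267  0.703
  f8 >= 1 days 0–7 -0.402 0.112 -0.615 -0.203
  f0 >= 2 days 0–7  0.364 0.106  0.147  0.583
  f7 >= 1 days 0–7  0.346 0.101  0.149  0.546
  f2 >= 1 days 0–7  0.285 0.092  0.097  0.472
```

Each row is a first-week log hazard ratio: `f4 >= 2` means "count feature 4
at or above its cutoff of 2", and its mean 0.48 says such episodes carry
e^0.48 ≈ 1.6× the first-week readmission/death hazard, credible interval
excluded zero. These are the model's *exact* reasoning — in this synthetic
cohort the five listed predictors are precisely those with the largest
planted true effects (0.6, −0.5, 0.5, 0.45, 0.35). The same fitted object
yields cohort baseline-hazard tables (`cohort_baseline_table`), per-cohort
placement effects (`treatment_effect_table`), exact per-episode
attributions (`ground_truth_attribution`) and a KernelSHAP harness for
contrasting them with post-hoc explanations.

A command-line interface mirrors the workflow:

```
quiltsurv simulate --seed 1 --n 20000 --out sim/
quiltsurv fit --data sim/episodes.csv --out model/ --batch-size 1000
quiltsurv evaluate --model model/ --data sim/episodes.csv --horizons 30,90 --out eval/
quiltsurv explain --model model/ --data sim/episodes.csv --method shap --row 7
```

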