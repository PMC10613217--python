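# rlconf

Computational modelling of **valence-biased confidence in human
reinforcement learning**: a complete, tested stack for simulating a
valence × information probabilistic instrumental-learning task with
incentivized confidence reports, fitting a factorial space of Q-learning
and confidence models, and comparing them with random-effects Bayesian
model selection.

It is aimed at computational cognitive scientists who want to (a) analyze
trial-level bandit data with confidence ratings, (b) run parameter/model
recovery studies for this model class, or (c) export model-derived
trial-by-trial regressors for downstream (e.g., neuroimaging) analyses.

## The task

Participants (or synthetic agents) repeatedly choose between two symbols in
four fixed contexts crossing **outcome valence** (gain: +1.0/+0.1 €; loss:
−1.0/−0.1 €) with **feedback information** (partial: chosen outcome only;
complete: both outcomes). Each symbol pays its better magnitude with
reciprocal 75%/25% probabilities. Three runs of 80 trials are followed by a
28-pair transfer phase without feedback. Confidence (50–100%, 5% steps) is
elicited every trial and incentivized by a matching-probability lottery,
which makes truthful probability reporting payout-optimal.

## The models

**Learning** — ten Q-learning variants built from two mechanisms:

- *relative* (context-dependent) learning: prediction errors are centered
  on a learned context value, `δ = R − V(s) − Q(s, c)`, with
  `V(s) ← V(s) + α_V ((R_c + R_u)/2 − V(s))`. In partial feedback the
  missing `R_u` is replaced by an inferred stand-in `X*` ∈ {0, Q(s,u), last
  seen outcome, w·¬R} where ¬R is the *imaginary forgone outcome*
  (complementary magnitude, sign of V);
- *asymmetric* (choice-confirmatory) updating: confirmatory prediction
  errors (positive chosen, negative unchosen) are weighted by `α_CON`,
  disconfirmatory ones by `α_DIS`.

Choices follow a softmax on the Q difference with inverse temperature β;
transfer choices use the frozen end-of-learning Q values.

**Confidence** — logit-scale regressions on the learning latents:

    logit(conf_t) = B₀ + B_|dQ| |Qc−Qu| + B_x · bias_t + B_prev conf_{t−1} + ε

with the bias term one of {0, Qc+Qu, Qc, V}. A positive chosen-value (Qc)
bias reproduces the empirical signature of this task family: higher
confidence when seeking gains than avoiding losses at matched difficulty
and accuracy.

**Inference** — per-subject MAP estimation (L-BFGS-B, multi-start;
Beta(1.1, 1.1) priors on rates, Gamma(1.2, 5) on β), Laplace approximation
to the log model evidence, robust (bisquare IRLS) confidence fits scored by
BIC, and random-effects group BMS yielding expected frequencies,
exceedance probabilities, the Bayes omnibus risk, and protected exceedance
probabilities.

## Worked example

```python
from rlconf import TaskConfig, simulate_cohort, rm_anova_2x2, RLModelMAP
from rlconf.stats import condition_summary, to_condition_matrix

cfg = TaskConfig(seed=1)                      # 40 agents, 3 runs x 80 trials
trials = simulate_cohort(cfg)
summary = condition_summary(trials)
print(rm_anova_2x2(to_condition_matrix(summary, "confidence")).round(4))
print(rm_anova_2x2(to_condition_matrix(summary, "accuracy")).round(4))

sub = trials[trials["subject"] == 0]
fit = RLModelMAP(model="relasym-imag", n_starts=10, random_state=0).fit(sub)
print({k: round(v, 3) for k, v in fit.params_.items()})
print("log evidence:", round(fit.log_evidence_, 2))
```

prints

```
        effect         F  df1  df2    p
0      valence  245.2078    1   39  0.0
1  information  222.4161    1   39  0.0
2  interaction  100.3002    1   39  0.0
        effect        F  df1  df2       p
0      valence   0.0000    1   39  1.0000
1  information  65.6630    1   39  0.0000
2  interaction   1.1626    1   39  0.2876
{'alpha_con': 0.333, 'alpha_dis': 0.152, 'alpha_v': 0.114, 'w': 0.934, 'beta': 3.963}
log evidence: -102.07
```

i.e. the simulated cohort shows a strong valence effect on *confidence*
(F₁,₃₉ = 245.2) but none on *accuracy* (F₁,₃₉ = 0.0), while feedback
information moves accuracy (F₁,₃₉ = 65.7) — the dissociation this model
class is built to capture. The MAP fit of agent 0 recovers confirmatory
asymmetry (`alpha_con > alpha_dis`) and a moderate inverse temperature.

A thin CLI wraps the same pipeline:

```bash
rlconf simulate --seed 1 --subjects 40 --out out/
rlconf fit-rl --seed 1 --out out/
rlconf bms --seed 1 --out out/
rlconf stats --seed 1 --out out/
```

## Layout

- `rlconf.task` / `rlconf.simulate` — design construction, outcome draws,
  matching-probability bonus, synthetic agents and cohorts
- `rlconf.models` — the ten-model space as pure state-transition and
  likelihood functions (numba-accelerated sequential pass)
- `rlconf.confidence` — confidence design matrices and predictions
- `rlconf.fitting` — `RLModelMAP`, `ConfidenceRegression`, Laplace evidence
- `rlconf.bms` — `BayesianModelSelection` (EF / EP / BOR / pEP)
- `rlconf.stats` — condition summaries, 2×2 repeated-measures ANOVA,
  t-tests, robust regression
- `rlconf.recovery` — parameter- and model-recovery suites
- `rlconf.pipeline` / `rlconf.cli` — orchestration, manifests, CLI

See `docs/methods.md` for the modelling and numerical details.
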