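# Methods

## Task model

The simulated experiment is a two-armed bandit with four fixed contexts
crossing outcome valence (gain / loss) and feedback information (partial /
complete). Defaults: 40 subjects, 3 runs, 20 trials per context per run
(80-trial runs), outcome magnitudes ±1.0 / ±0.1 € with reciprocal 75/25
probabilities per option, a 28-pair transfer phase, confidence on a
50–100% grid in 5% steps, and a 5 € confidence bonus.

Context order within a run is a uniform random permutation of the label
vector, seeded per (master seed, subject, run); no constraint on run
lengths of repeated contexts is imposed. Both options' outcomes are drawn
on every trial; the partial-information condition only *hides* the
unchosen outcome from the record (the complete-feedback update rules and
the payout bookkeeping need both draws to exist). The matching-probability
bonus compares the reported confidence p with a lottery number
r ~ U[0.5, 1]: if p ≥ r the bonus is paid when the choice was objectively
correct, otherwise it is paid with probability r. Its expected payout,
`5(2q(p−½) + (1−p²))`, is maximized at p = q, so truthful reporting is
optimal; the test suite verifies this by brute force over the grid.

## Learning models

The space holds ten models in four families. All Q values, context values
V, and last-outcome stores start at 0 — the conventional neutral
initialization, which also makes gain and loss contexts symmetric a
priori.

- ABS: `Q(s,c) ← Q + α_c δ_c`, `Q(s,u) ← Q + α_u δ_u`, with δ = R − Q.
  Both learning rates are free parameters.
- REL: prediction errors centered on the context value,
  δ = R − V(s) − Q; V updated with rate α_V toward the mean of the two
  outcomes, `(R_c + R_u)/2`. With partial feedback the unobserved R_u is
  replaced **in the V update only** by an inferred stand-in X*, one of:
  0, the current Q(s,u), the last outcome ever displayed for that symbol
  (0 if never seen; since symbols are context-specific, in partial
  contexts this store can only be refreshed when the symbol is chosen),
  or w·¬R with the imaginary forgone outcome
  ¬R = sign(V) × (1 if |R_c| = 0.1 else 0.1), 0 when V = 0.
  The unchosen Q is never updated on partial trials — its outcome is
  unobserved and the delta rule requires it.
- ASYM: the chosen-option rate is α_CON for δ_c > 0 and α_DIS for
  δ_c < 0; for the unchosen option the mapping mirrors (α_CON for
  δ_u < 0), so "confirmatory" always means evidence favoring the choice
  made.
- RELASYM: both mechanisms; the V update keeps the single symmetric rate
  α_V (asymmetry applies to Q updates only).

Choice probabilities are a softmax on the Q difference,
`P(A) = 1/(1 + exp(−β(Q_A − Q_B)))` — probability increases with the
option's own value — clamped to [1e−12, 1 − 1e−12] before logs. The
transfer phase uses the same β on Q values frozen at the end of learning;
its likelihood is a sum over exchangeable trials, so it is invariant to
transfer trial order.

Parameter bounds: rates and w in (0, 1), β ≥ 0 (optimization box
[1e−6, 1−1e−6] and [1e−6, 100]).

## Confidence models

Confidence is the inverse logit of a linear predictor with the choice
difficulty |Qc − Qu|, one of four bias terms (none / Qc+Qu / Qc / V), and
— learning phase only — the previous rating, which captures the serial
dependency of confidence judgments. The none-variant drops the bias
column entirely rather than fitting a zero column, so BIC dimension
counts are honest. At each session's first trial the previous rating is
set to 0.75, the reporting-scale midpoint. For a transfer pair the
context value is the mean of the two symbols' end-of-learning V values.
Ratings are clipped by ε = 1e−3 before the logit so that 100% reports
(common in practice) stay finite; ε is this package's choice.

## Estimation

RL models are fit per subject by minimizing the negative log posterior
(choice negative log-likelihood minus log prior density). Priors:
Beta(1.1, 1.1) on learning rates and w, Gamma(shape 1.2, scale 5) on β
(mean 6). Optimization is bounded L-BFGS-B from 10 random starts drawn
from the priors (the number of restarts is a package default; the fit is
deterministic given `random_state`). The log model evidence is the
Laplace approximation `−nLPP + (df/2)log 2π − ½ log|H|` with H the
central-finite-difference Hessian of the objective at the MAP (step
1e−4·max(|θᵢ|, 1), shrunk near bounds, symmetrized; escalating ×10 jitter
from 1e−6·I if not positive definite, flagged on the estimator).

Confidence regressions are fit by iteratively reweighted least squares
with the Tukey bisquare weight function (tuning 4.685, coefficient
tolerance 1e−8) on logit-transformed ratings. The reported log-likelihood
is the plain Gaussian likelihood of the residuals at the converged
coefficients with maximum-likelihood variance — the minimal reading
consistent with treating the robust fit as likelihood maximization — and
feeds BIC = n log(m) − 2 LL (n parameters, m trials). When a fit is
numerically perfect the bisquare scale collapses to rounding noise, so
robust weights are reported as 1 in that degenerate case.

## Group-level model selection

Random-effects BMS treats model identity as a random effect with a
symmetric Dirichlet prior (α₀ = 1) on population model frequencies,
iterating the standard variational updates to a concentration change
below 1e−6. Exceedance probabilities are estimated from 10⁶ seeded
Dirichlet draws. The Bayes omnibus risk is the posterior probability of
the equal-frequency null from the free-energy comparison of the null
(each subject's model drawn uniformly) and the Dirichlet alternative;
the exact estimator is this package's commitment to the standard
formulation. Protected exceedance is `EP(1−BOR) + BOR/K`. Confidence
models enter with log evidence −BIC/2.

## Behavioral statistics

Accuracy counts choices of the higher-expected-value symbol; calibration
is mean confidence minus mean accuracy. The 2×2 within-subject ANOVA is
computed through orthogonal paired contrasts (valence, information,
interaction), where each effect's F with df (1, n−1) equals the square of
the corresponding paired t — exact for single-df effects, with no
sphericity machinery needed; the test suite cross-checks it against an
independent repeated-measures ANOVA implementation and verifies nominal
type-I error (5% ± 1% over 2000 null replicates). Degenerate
(zero-variance) t-test inputs raise rather than returning an undefined
statistic. The inter-individual robust regression reuses the bisquare
IRLS core.

## Synthetic cohort

The default generator emulates the study conditions with agents driven by
the relative-asymmetric model (weighted-imaginary counterfactual) and a
Qc-biased confidence regression. Population means — α_CON = 0.35,
α_DIS = 0.12, α_V = 0.25, w = 0.35, β = 5; confidence B₀ = −0.6,
B_|dQ| = 2.0, B_x = 1.5, B_prev = 1.2, report noise 0.5 logit units —
were chosen once as values a practitioner would call realistic for this
task class: moderate confirmatory asymmetry, *slow* context-value
learning (which leaves a transient valence signature in the Q values and
hence, through the positive Qc coefficient, the gain > loss confidence
gap at matched accuracy), and mid-range decision noise yielding ~85%
asymptotic accuracy. Per-agent heterogeneity is mild jitter around these
means. Simulated ratings are rounded to the nearest 5% grid point (ties
up); reaction times are not modeled and are recorded as missing, so RT
analyses only apply to real data.

What the generator does *not* emulate: sequential effects beyond the
confidence autocorrelation, lapses/attention drifts, RT–confidence
coupling, and individual differences in grid usage. Tests passing on
synthetic cohorts therefore validate the estimation machinery and the
qualitative mechanism, not any claim about a particular empirical
dataset. External datasets enter through the documented CSV trial schema
(a column-mapping exercise left to the user; the package never downloads
data).

## Problem sizes and numerical choices in the shipped checks

The recovery suites run at the study scale — 240 learning + 28 transfer
trials per agent; 40 agents (parameters drawn from the fitting priors)
for parameter recovery, 3 generating models × 20 agents for model
recovery with one representative model per family as candidates. The
acceptance script fits the full ten-model space to 20 agents. The
likelihood pass is numba-compiled; an equivalent pure-Python per-trial
API is the readable reference, and the two are asserted equal to 1e−10.

## Known limitations

- No hierarchical/empirical-Bayes pooling across subjects; fits are
  per-subject MAP.
- The Laplace evidence is a local approximation; multimodal posteriors
  (e.g., very low β) are summarized by the best mode only.
- The four-model confidence comparison assumes the RL latents of a single
  winning model; uncertainty in that first-stage choice is not
  propagated.
- Family-level BMS inference beyond the flat model list is not
  implemented.
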