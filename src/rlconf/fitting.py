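"""MAP estimation, Laplace model evidence, and robust confidence fits.

RL model parameters are estimated by minimizing the negative log posterior
probability (choice negative log-likelihood minus log prior density) with
bounded L-BFGS-B from several random starts.  Priors follow the common
broad choices: Beta(1.1, 1.1) on learning rates and the counterfactual
weight, Gamma(shape 1.2, scale 5) on the inverse temperature.  The log
model evidence is approximated with the Laplace formula

    LAME = -nLPP + (df/2) log(2 pi) - (1/2) log |H|

where H is the (finite-difference, regularized) Hessian of the objective
at the MAP.

Confidence models are fit by iteratively reweighted least squares with a
bisquare weight function on logit-transformed ratings; their evidence is
approximated by BIC = n log(m) - 2 LL with a Gaussian log-likelihood at
the converged coefficients.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from . import models
from ._kernels import learning_pass, transfer_loglik
from ._pack import pack_learning, pack_transfer
from .confidence import ConfSpec, logit_clip, inverse_logit
from .models import (
    ModelSpec,
    _FAMILY_CODE,
    _VARIANT_CODE,
    _check_learning_order,
    get_model,
    params_from_vector,
)

BETA_MAX = 100.0
_EDGE = 1e-6


class PriorSpec:
    """Independent priors: Beta(1.1, 1.1) on rates and w, Gamma(1.2, scale 5)
    on the inverse temperature."""

    beta_prior = stats.beta(1.1, 1.1)
    gamma_prior = stats.gamma(1.2, scale=5.0)
    # closed-form log-density constants (the optimizer calls logpdf in its
    # inner loop, so the scipy frozen distributions are used for sampling only)
    _beta_a = _beta_b = 1.1
    _log_beta_norm = float(special.betaln(1.1, 1.1))
    _gamma_k, _gamma_scale = 1.2, 5.0
    _log_gamma_norm = float(special.gammaln(1.2) + 1.2 * math.log(5.0))

    def _dist(self, name: str):
        return self.gamma_prior if name == "beta" else self.beta_prior

    def logpdf(self, theta: np.ndarray, names: tuple[str, ...]) -> float:
        total = 0.0
        for name, x in zip(names, theta):
            if name == "beta":
                if x <= 0:
                    return -math.inf
                total += (
                    (self._gamma_k - 1.0) * math.log(x)
                    - x / self._gamma_scale
                    - self._log_gamma_norm
                )
            else:
                if not 0.0 < x < 1.0:
                    return -math.inf
                total += (
                    (self._beta_a - 1.0) * math.log(x)
                    + (self._beta_b - 1.0) * math.log1p(-x)
                    - self._log_beta_norm
                )
        return total

    def sample(self, names: tuple[str, ...], rng: np.random.Generator) -> np.ndarray:
        draw = np.array(
            [self._dist(n).rvs(random_state=rng) for n in names], dtype=float
        )
        return np.clip(draw, _EDGE, [BETA_MAX if n == "beta" else 1 - _EDGE for n in names])


class FlatPrior(PriorSpec):
    """Improper flat prior: nLPP reduces to the negative log-likelihood."""

    def logpdf(self, theta, names) -> float:
        return 0.0

    def sample(self, names, rng) -> np.ndarray:
        return np.array(
            [rng.uniform(0.05, BETA_MAX / 2 if n == "beta" else 0.95) for n in names]
        )


def default_bounds(spec: ModelSpec) -> list[tuple[float, float]]:
    return [
        (_EDGE, BETA_MAX) if n == "beta" else (_EDGE, 1.0 - _EDGE)
        for n in spec.param_names
    ]


class _PackedSubject:
    """Pre-packed arrays for fast repeated likelihood evaluation."""

    def __init__(self, trials: pd.DataFrame):
        learning = _check_learning_order(trials)
        self.learning = pack_learning(learning)
        transfer = trials[trials["phase"] == "transfer"]
        self.transfer = pack_transfer(transfer) if len(transfer) else None
        self.n_trials = len(learning) + (len(transfer) if transfer is not None else 0)


@lru_cache(maxsize=None)
def _theta5_indices(spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Scatter map from a model's free-parameter vector into the kernel's
    fixed (a1, a2, alpha_v, w, beta) slot layout."""
    dst = {name: i for i, name in enumerate(
        ("alpha_con", "alpha_dis", "alpha_v", "w", "beta")
    )}
    dst.update({"alpha_c": 0, "alpha_u": 1})
    pairs = [(i, dst[name]) for i, name in enumerate(spec.param_names)]
    src, tgt = zip(*pairs)
    return np.array(src), np.array(tgt)


def _packed_loglik(spec: ModelSpec, theta: np.ndarray, packed: _PackedSubject,
                   want_latents: bool = False):
    theta5 = np.zeros(5)
    src, tgt = _theta5_indices(spec)
    theta5[tgt] = np.asarray(theta)[src]
    variant = (
        -1 if spec.counterfactual_variant is None
        else _VARIANT_CODE[spec.counterfactual_variant]
    )
    latents, q_end, v_end, ll = learning_pass(
        _FAMILY_CODE[spec.family], variant, theta5, *packed.learning
    )
    if packed.transfer is not None:
        ll += transfer_loglik(theta5[4], q_end, *packed.transfer)
    if want_latents:
        return ll, latents, q_end, v_end
    return ll


def nlpp(
    spec: ModelSpec | str,
    theta: np.ndarray | dict[str, float],
    trials: pd.DataFrame | _PackedSubject,
    priors: PriorSpec | None = None,
) -> float:
    """Negative log posterior probability of one parameter vector.

    Returns +inf (not an exception) when the prior density vanishes at the
    support boundary.
    """
    spec = get_model(spec)
    if isinstance(theta, dict):
        theta = np.array([theta[n] for n in spec.param_names], dtype=float)
    packed = trials if isinstance(trials, _PackedSubject) else _PackedSubject(trials)
    priors = PriorSpec() if priors is None else priors
    lp = priors.logpdf(np.asarray(theta, dtype=float), spec.param_names)
    if not np.isfinite(lp):
        return float("inf")
    return -_packed_loglik(spec, np.asarray(theta, dtype=float), packed) - lp


def minimize_multistart(
    fun,
    bounds: list[tuple[float, float]],
    n_starts: int,
    rng: np.random.Generator,
    sampler=None,
):
    """Bounded L-BFGS-B from random interior starts; returns the best result
    and the number of starts that converged."""
    best = None
    n_ok = 0
    for _ in range(n_starts):
        if sampler is not None:
            x0 = sampler(rng)
        else:
            x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(fun, x0, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun):
            n_ok += int(bool(res.success))
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"all {n_starts} optimization starts failed (non-finite objective)"
        )
    return best, n_ok


def numerical_hessian(
    objective,
    theta: np.ndarray,
    bounds: list[tuple[float, float]] | None = None,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central finite-difference Hessian, symmetrized.

    Steps are ``rel_step * max(|theta_i|, 1)``, shrunk where needed so the
    evaluation points stay strictly inside the bounds.
    """
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    step = rel_step * np.maximum(np.abs(theta), 1.0)
    if bounds is not None:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        room = np.minimum(theta - lo, hi - theta) / 2.0
        step = np.maximum(np.minimum(step, room), 1e-9)
    H = np.empty((k, k))
    f0 = objective(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step[i]
        H[i, i] = (objective(theta + ei) - 2.0 * f0 + objective(theta - ei)) / step[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = step[j]
            fpp = objective(theta + ei + ej)
            fpm = objective(theta + ei - ej)
            fmp = objective(theta - ei + ej)
            fmm = objective(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step[i] * step[j])
    return (H + H.T) / 2.0


def _regularize_pd(H: np.ndarray, jitter0: float = 1e-6):
    """Escalating-jitter regularization until positive definite."""
    H = (H + H.T) / 2.0
    jitter = 0.0
    trial = jitter0
    while True:
        try:
            np.linalg.cholesky(H + jitter * np.eye(len(H)))
            return H + jitter * np.eye(len(H)), jitter
        except np.linalg.LinAlgError:
            jitter = trial
            trial *= 10.0
            if jitter > 1e12:
                raise RuntimeError("Hessian could not be regularized to PD")


def laplace_evidence(nlpp_min: float, hessian: np.ndarray) -> float:
    """Laplace approximation to the log model evidence at the MAP."""
    H, _ = _regularize_pd(np.asarray(hessian, dtype=float))
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("Hessian determinant is not positive and finite")
    df = len(H)
    return -nlpp_min + 0.5 * df * math.log(2.0 * math.pi) - 0.5 * logdet


class RLModelMAP(BaseEstimator):
    """MAP estimator of one RL model for one subject's trials.

    Parameters
    ----------
    model : str or ModelSpec, default "relasym-imag"
        Which of the ten models to fit.
    priors : PriorSpec, optional
        Parameter priors; defaults to the broad Beta/Gamma priors.
    n_starts : int, default 10
        Random restarts of the bounded quasi-Newton search.
    random_state : int, optional
        Seed for the restart draws; fitting is deterministic given it.

    Attributes (after fit)
    ----------------------
    theta_, params_ : MAP estimate (vector / named dict)
    nlpp_, loglik_ : objective and choice log-likelihood at the MAP
    hessian_ : finite-difference Hessian of the objective at the MAP
    log_evidence_ : Laplace approximation to the log model evidence
    latents_ : per-trial latent variables under the MAP parameters
    n_converged_ : restarts that reported convergence
    """

    def __init__(
        self,
        model: str | ModelSpec = "relasym-imag",
        priors: PriorSpec | None = None,
        n_starts: int = 10,
        random_state: int | None = None,
    ):
        self.model = model
        self.priors = priors
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "RLModelMAP":
        spec = get_model(self.model)
        priors = self.priors if self.priors is not None else PriorSpec()
        packed = _PackedSubject(X)
        bounds = default_bounds(spec)
        rng = np.random.default_rng(self.random_state)

        def objective(theta):
            lp = priors.logpdf(theta, spec.param_names)
            if not np.isfinite(lp):
                return float("inf")
            return -_packed_loglik(spec, theta, packed) - lp

        best, n_ok = minimize_multistart(
            objective, bounds, self.n_starts, rng,
            sampler=lambda r: priors.sample(spec.param_names, r),
        )
        self.spec_ = spec
        self.theta_ = np.asarray(best.x, dtype=float)
        self.params_ = params_from_vector(spec, self.theta_)
        self.nlpp_ = float(best.fun)
        self.n_converged_ = n_ok
        self.converged_ = n_ok > 0
        ll, latents, q_end, v_end = _packed_loglik(
            spec, self.theta_, packed, want_latents=True
        )
        self.loglik_ = float(ll)
        self.hessian_ = numerical_hessian(objective, self.theta_, bounds=bounds)
        self.log_evidence_ = laplace_evidence(self.nlpp_, self.hessian_)
        self.hessian_jitter_ = _regularize_pd(self.hessian_)[1]
        self.latents_, _ = models.run_model(spec, self.params_, X)
        self.n_trials_ = packed.n_trials
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Choice log-likelihood of ``X`` under the fitted parameters."""
        _, ll = models.run_model(self.spec_, self.params_, X)
        return ll


def fit_map(
    model: str | ModelSpec,
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    n_starts: int = 10,
    seed: int | None = None,
) -> RLModelMAP:
    """Functional wrapper over :class:`RLModelMAP`."""
    return RLModelMAP(
        model=model, priors=priors, n_starts=n_starts, random_state=seed
    ).fit(trials)


# -- robust confidence regression ---------------------------------------------


def _check_design(X: pd.DataFrame) -> np.ndarray:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        cols = ["const"] + list(X.columns)
        bad = [
            cols[j]
            for j in range(1, mat.shape[1])
            if np.linalg.matrix_rank(np.delete(mat, j, axis=1)) == np.linalg.matrix_rank(mat)
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return mat


class ConfidenceRegression(BaseEstimator):
    """Robust (bisquare IRLS) confidence regression on the logit scale.

    Ratings are clipped away from {0, 1} by ``eps`` and logit-transformed;
    coefficients are estimated by iteratively reweighted least squares with
    the Tukey bisquare weight function (tuning constant 4.685).  The model
    log-likelihood is the Gaussian likelihood of the residuals with
    maximum-likelihood variance, and BIC = n log(m) - 2 LL.
    """

    def __init__(
        self,
        bias: str = "qc",
        phase: str = "learning",
        eps: float = 1e-3,
        tuning: float = 4.685,
        tol: float = 1e-8,
        max_iter: int = 500,
    ):
        self.bias = bias
        self.phase = phase
        self.eps = eps
        self.tuning = tuning
        self.tol = tol
        self.max_iter = max_iter

    @property
    def spec(self) -> ConfSpec:
        return ConfSpec(bias=self.bias, phase=self.phase)

    def fit(self, X: pd.DataFrame, y) -> "ConfidenceRegression":
        spec = self.spec
        missing = set(spec.columns) - set(X.columns)
        if missing:
            raise ValueError(f"design lacks predictor columns {sorted(missing)}")
        X = X[list(spec.columns)]
        y = np.asarray(y, dtype=float)
        if len(X) < spec.n_params + 2:
            raise ValueError("too few observations for the confidence fit")
        mat = _check_design(X)
        z = logit_clip(y, self.eps)
        rlm = sm.RLM(z, mat, M=sm.robust.norms.TukeyBiweight(c=self.tuning))
        res = rlm.fit(conv="coefs", tol=self.tol, maxiter=self.max_iter)
        coef = np.asarray(res.params, dtype=float)
        self.params_ = {"const": coef[0], **dict(zip(X.columns, coef[1:]))}
        self.coef_ = coef[1:]
        self.intercept_ = coef[0]
        self.weights_ = np.asarray(res.weights, dtype=float)
        resid = z - mat @ coef
        # a numerically perfect fit has no outliers: the MAD scale collapses
        # to rounding noise and the raw weights are meaningless
        if np.max(np.abs(resid)) < 1e-8 * max(1.0, float(np.std(z))):
            self.weights_ = np.ones_like(self.weights_)
        m = len(y)
        sigma2 = float(np.mean(resid**2))
        self.sigma_ = math.sqrt(sigma2)
        self.loglik_ = -0.5 * m * (math.log(2.0 * math.pi * sigma2) + 1.0)
        self.nobs_ = m
        self.nparams_ = spec.n_params
        self.bic_ = self.nparams_ * math.log(m) - 2.0 * self.loglik_
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        lin = np.full(len(X), self.intercept_)
        for col, b in zip(self.spec.columns, self.coef_):
            lin += b * X[col].to_numpy(dtype=float)
        return inverse_logit(lin)


def fit_confidence(
    spec: ConfSpec, rows: pd.DataFrame, ratings
) -> ConfidenceRegression:
    """Functional wrapper over :class:`ConfidenceRegression`."""
    return ConfidenceRegression(bias=spec.bias, phase=spec.phase).fit(rows, ratings)
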