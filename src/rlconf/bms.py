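"""Random-effects Bayesian model selection over per-subject log evidences.

Model identity is treated as a random effect: each subject's data may come
from a different model, and the population frequencies r of the K models
carry a Dirichlet prior (alpha0 = 1 per model).  A variational scheme
alternates between posterior model attributions per subject and the
Dirichlet concentration update until convergence.  Reported quantities:

* EF — expected model frequencies, alpha / sum(alpha);
* EP — exceedance probabilities, P(r_k > r_j for all j != k), estimated by
  seeded Dirichlet Monte Carlo;
* BOR — Bayes omnibus risk, the posterior probability of the null
  hypothesis that all frequencies are equal, from the free-energy
  comparison of the null and the Dirichlet alternative;
* pEP — protected exceedance probabilities,
  pEP = EP (1 - BOR) + BOR / K.

When models are compared through BIC (the confidence regressions), the log
evidence fed in is -BIC/2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp
from sklearn.base import BaseEstimator


def _as_matrix(evidence) -> tuple[np.ndarray, list[str]]:
    if isinstance(evidence, pd.DataFrame):
        return evidence.to_numpy(dtype=float), [str(c) for c in evidence.columns]
    arr = np.asarray(evidence, dtype=float)
    return arr, [f"m{i}" for i in range(arr.shape[1])]


class BayesianModelSelection(BaseEstimator):
    """Random-effects group-level model comparison.

    Parameters
    ----------
    alpha0 : float, default 1.0
        Symmetric Dirichlet prior concentration per model.
    tol : float, default 1e-6
        Convergence threshold on the concentration change.
    n_samples : int, default 1_000_000
        Dirichlet Monte-Carlo draws for the exceedance probabilities.
    random_state : int, default 0
        Seed of the Monte-Carlo draws.

    Attributes (after fit)
    ----------------------
    alpha_ : posterior Dirichlet concentrations
    ef_ : expected model frequencies
    ep_ : exceedance probabilities
    bor_ : Bayes omnibus risk
    pep_ : protected exceedance probabilities
    attributions_ : per-subject posterior model probabilities
    """

    def __init__(
        self,
        alpha0: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 100_000,
        n_samples: int = 1_000_000,
        random_state: int = 0,
    ):
        self.alpha0 = alpha0
        self.tol = tol
        self.max_iter = max_iter
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, X, y=None) -> "BayesianModelSelection":
        lme, labels = _as_matrix(X)
        if lme.ndim != 2 or lme.shape[1] < 2:
            raise ValueError("evidence matrix must be subjects x (>=2) models")
        if not np.isfinite(lme).all():
            raise ValueError("evidence matrix contains non-finite entries")
        n, k = lme.shape
        alpha0 = np.full(k, float(self.alpha0))
        alpha = alpha0.copy()
        for _ in range(self.max_iter):
            logu = lme + digamma(alpha) - digamma(alpha.sum())
            g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
            alpha_new = alpha0 + g.sum(axis=0)
            if np.max(np.abs(alpha_new - alpha)) < self.tol:
                alpha = alpha_new
                break
            alpha = alpha_new
        self.model_labels_ = labels
        self.alpha_ = alpha
        self.attributions_ = g
        self.ef_ = alpha / alpha.sum()
        self.ep_ = exceedance_probability(
            alpha, n_samples=self.n_samples, seed=self.random_state
        )
        self.f1_ = _free_energy_alternative(lme, alpha0, alpha, g)
        self.f0_ = _free_energy_null(lme)
        self.bor_ = float(1.0 / (1.0 + np.exp(self.f1_ - self.f0_)))
        self.pep_ = protected_ep(self.ep_, self.bor_, k)
        return self

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_labels_,
                "alpha": self.alpha_,
                "ef": self.ef_,
                "ep": self.ep_,
                "pep": self.pep_,
            }
        )


def exceedance_probability(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int = 0,
    chunk: int = 1_000_000,
) -> np.ndarray:
    """P(r_k is the largest frequency) under Dirichlet(alpha), by Monte Carlo."""
    alpha = np.asarray(alpha, dtype=float)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(alpha))
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=len(alpha))
        done += m
    return counts / n_samples


def _free_energy_alternative(
    lme: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray, g: np.ndarray
) -> float:
    """Variational free energy of the random-effects (Dirichlet) model."""
    psi = digamma(alpha) - digamma(alpha.sum())
    expected_log_joint = float(np.sum(g * (lme + psi)))
    entropy_models = -float(np.sum(g * np.log(np.maximum(g, 1e-300))))
    kl_dirichlet = (
        gammaln(alpha.sum())
        - gammaln(alpha0.sum())
        - np.sum(gammaln(alpha))
        + np.sum(gammaln(alpha0))
        + float(np.sum((alpha - alpha0) * psi))
    )
    return expected_log_joint + entropy_models - kl_dirichlet


def _free_energy_null(lme: np.ndarray) -> float:
    """Log evidence of the null model: every subject's model drawn with
    equal probability 1/K."""
    n, k = lme.shape
    return float(np.sum(logsumexp(lme, axis=1) - np.log(k)))


def protected_ep(ep: np.ndarray, bor: float, k: int) -> np.ndarray:
    """Exceedance probabilities shrunk toward chance by the omnibus risk."""
    return np.asarray(ep, dtype=float) * (1.0 - bor) + bor / k


def rfx_bms(
    evidence, n_samples: int = 1_000_000, seed: int = 0
) -> BayesianModelSelection:
    """Functional wrapper over :class:`BayesianModelSelection`."""
    return BayesianModelSelection(n_samples=n_samples, random_state=seed).fit(evidence)
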