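"""Confidence regressions on RL latent variables.

Confidence is modeled as the inverse logit of a linear combination of
choice difficulty |Qc - Qu|, a valence-bias term (one of: none, the summed
option values Qc + Qu, the chosen value Qc, or the context value V), and —
in the learning phase only — the previous trial's rating, which captures
the serial dependency of confidence judgments.  In the transfer phase the
context value of a pair is the mean of the two symbols' end-of-learning
context values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONF_BIASES = ("none", "sumq", "qc", "v")
PHASES = ("learning", "transfer")

#: previous-rating stand-in at each session's first trial (scale midpoint)
CONF_PREV_INIT = 0.75


@dataclass(frozen=True)
class ConfSpec:
    """One confidence model: bias variant x phase."""

    bias: str = "qc"
    phase: str = "learning"

    def __post_init__(self) -> None:
        if self.bias not in CONF_BIASES:
            raise ValueError(f"bias must be one of {CONF_BIASES}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")

    @property
    def columns(self) -> tuple[str, ...]:
        """Predictor columns (intercept excluded)."""
        cols = ("dq_abs",)
        if self.bias != "none":
            cols = cols + ("bias",)
        if self.phase == "learning":
            cols = cols + ("conf_prev",)
        return cols

    @property
    def n_params(self) -> int:
        return 1 + len(self.columns)


def logit_clip(y, eps: float = 1e-3) -> np.ndarray | float:
    """Logit transform with clipping so ratings of exactly 1 stay finite."""
    y = np.clip(y, eps, 1.0 - eps)
    return np.log(y / (1.0 - y))


def inverse_logit(x) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def transfer_context_value(v_end_c: float, v_end_d: float) -> float:
    """Generalized context value of a transfer pair: the mean of the two
    end-of-learning context values."""
    return (v_end_c + v_end_d) / 2.0


def build_predictors(
    latents: pd.DataFrame,
    ratings: pd.Series | np.ndarray,
    spec: ConfSpec,
    runs: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Design matrix for a confidence regression.

    ``latents`` must carry Qc, Qu and (for the V bias) V columns aligned
    with ``ratings``.  For the learning phase the previous rating is lagged
    within each session (``runs`` labels), with the scale midpoint 0.75 at
    each session's first trial.
    """
    ratings = np.asarray(ratings, dtype=float)
    if len(latents) != len(ratings):
        raise ValueError("latents and ratings are misaligned")
    qc = latents["Qc"].to_numpy(dtype=float)
    qu = latents["Qu"].to_numpy(dtype=float)
    out = pd.DataFrame(index=latents.index)
    out["dq_abs"] = np.abs(qc - qu)
    if spec.bias == "sumq":
        out["bias"] = qc + qu
    elif spec.bias == "qc":
        out["bias"] = qc
    elif spec.bias == "v":
        out["bias"] = latents["V"].to_numpy(dtype=float)
    if spec.phase == "learning":
        prev = np.empty(len(ratings))
        prev[0] = CONF_PREV_INIT
        prev[1:] = ratings[:-1]
        if runs is not None:
            runs = np.asarray(runs)
            first = np.ones(len(ratings), dtype=bool)
            first[1:] = runs[1:] != runs[:-1]
            prev[first] = CONF_PREV_INIT
        out["conf_prev"] = prev
    return out


def predict_confidence(rows: pd.DataFrame, params: dict[str, float]) -> np.ndarray:
    """Noise-free predicted ratings: inverse logit of the linear predictor.

    ``params`` maps ``const`` plus the predictor column names to
    coefficients.
    """
    lin = np.full(len(rows), params.get("const", 0.0), dtype=float)
    for col in rows.columns:
        lin += params.get(col, 0.0) * rows[col].to_numpy(dtype=float)
    return inverse_logit(lin)
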