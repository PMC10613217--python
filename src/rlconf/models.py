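"""The ten-model reinforcement-learning space.

Four families share a delta-rule backbone:

* ABS — absolute Q-learning: ``Q <- Q + alpha * (R - Q)`` with separate
  learning rates for the chosen and the (complete-feedback) unchosen option.
* REL — relative (context-dependent) learning: prediction errors are
  centered on a learned context value V, itself updated toward the average
  of the two outcomes.
* ASYM — asymmetric (choice-confirmatory) updating: a confirmatory rate
  weights positive chosen / negative unchosen prediction errors, a
  disconfirmatory rate the opposite signs.
* RELASYM — both mechanisms combined.

In partial-feedback contexts the unchosen outcome is unobserved; the
relative families replace it, in the context-value update only, with an
inferred stand-in X* taking one of four forms: 0, the unchosen option's
current Q value, the last outcome ever displayed for that symbol, or a
weighted *imaginary forgone outcome* whose magnitude complements the
received one and whose sign follows the context value.

Choices follow a softmax on the Q difference with inverse temperature beta;
transfer-phase choices use the same softmax on the end-of-learning Q values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import CONTEXTS, context_information

MISSING = float("nan")

FAMILIES = ("ABS", "REL", "ASYM", "RELASYM")
VARIANTS = ("zero", "Qu", "last_outcome", "weighted_imaginary")

_FAMILY_CODE = {f: i for i, f in enumerate(FAMILIES)}
_VARIANT_CODE = {v: i for i, v in enumerate(VARIANTS)}


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one model in the space."""

    name: str
    family: str
    counterfactual_variant: str | None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        relative = self.family in ("REL", "RELASYM")
        if relative and self.counterfactual_variant not in VARIANTS:
            raise ValueError(f"{self.family} requires a counterfactual variant")
        if not relative and self.counterfactual_variant is not None:
            raise ValueError(f"{self.family} admits no counterfactual variant")

    @property
    def relative(self) -> bool:
        return self.family in ("REL", "RELASYM")

    @property
    def asymmetric(self) -> bool:
        return self.family in ("ASYM", "RELASYM")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = (
            ("alpha_con", "alpha_dis") if self.asymmetric else ("alpha_c", "alpha_u")
        )
        if self.relative:
            names = names + ("alpha_v",)
        if self.counterfactual_variant == "weighted_imaginary":
            names = names + ("w",)
        return names + ("beta",)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _space() -> dict[str, ModelSpec]:
    space: dict[str, ModelSpec] = {}
    space["abs"] = ModelSpec("abs", "ABS", None)
    space["asym"] = ModelSpec("asym", "ASYM", None)
    short = {"zero": "zero", "Qu": "qu", "last_outcome": "last", "weighted_imaginary": "imag"}
    for family, prefix in (("REL", "rel"), ("RELASYM", "relasym")):
        for variant, tag in short.items():
            name = f"{prefix}-{tag}"
            space[name] = ModelSpec(name, family, variant)
    return space


#: the ten models, keyed by short name (abs, asym, rel-*, relasym-*)
MODEL_SPACE: dict[str, ModelSpec] = _space()


def get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODEL_SPACE[model]
    except KeyError:
        raise KeyError(
            f"unknown model {model!r}; choose from {sorted(MODEL_SPACE)}"
        ) from None


def validate_params(spec: ModelSpec, params: dict[str, float]) -> None:
    extra = set(params) - set(spec.param_names)
    missing = set(spec.param_names) - set(params)
    if extra or missing:
        raise ValueError(
            f"model {spec.name} takes parameters {spec.param_names}; "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    for name, value in params.items():
        if name == "beta":
            if not value >= 0:
                raise ValueError("beta must be >= 0")
        elif not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class LearnerState:
    """Running values of one learner: per-(context, option) Q, per-context
    V, and the last displayed outcome per symbol (for the last_outcome
    counterfactual).  Everything starts at zero."""

    Q: dict[tuple[str, bool], float] = field(
        default_factory=lambda: {(c, g): 0.0 for c in CONTEXTS for g in (True, False)}
    )
    V: dict[str, float] = field(default_factory=lambda: {c: 0.0 for c in CONTEXTS})
    last_outcome: dict[tuple[str, bool], float] = field(
        default_factory=lambda: {(c, g): 0.0 for c in CONTEXTS for g in (True, False)}
    )

    def copy(self) -> "LearnerState":
        return LearnerState(dict(self.Q), dict(self.V), dict(self.last_outcome))


def imaginary_outcome(r_chosen: float, v: float) -> float:
    """Imaginary forgone outcome: complementary magnitude, sign of the
    context value; zero when the context value is exactly zero."""
    magnitude = abs(r_chosen)
    if not (math.isclose(magnitude, 0.1) or math.isclose(magnitude, 1.0)):
        raise ValueError(f"unexpected outcome magnitude {magnitude}")
    if v == 0.0:
        return 0.0
    complement = 1.0 if math.isclose(magnitude, 0.1) else 0.1
    return complement if v > 0 else -complement


def counterfactual_x(
    spec: ModelSpec,
    params: dict[str, float],
    state: LearnerState,
    context: str,
    chosen_good: bool,
    r_chosen: float,
) -> float:
    """Stand-in X* for the unobserved unchosen outcome (partial feedback)."""
    if context_information(context) != "partial":
        raise ValueError("counterfactual inference applies to partial contexts only")
    if not spec.relative:
        raise ValueError("only relative families infer a counterfactual")
    variant = spec.counterfactual_variant
    if variant == "zero":
        return 0.0
    if variant == "Qu":
        return state.Q[(context, not chosen_good)]
    if variant == "last_outcome":
        return state.last_outcome[(context, not chosen_good)]
    # weighted imaginary forgone outcome
    return params["w"] * imaginary_outcome(r_chosen, state.V[context])


def prediction_errors(
    spec: ModelSpec,
    params: dict[str, float],
    state: LearnerState,
    context: str,
    chosen_good: bool,
    r_chosen: float,
    r_unchosen: float | None,
) -> tuple[float, float, float]:
    """Per-trial prediction errors (delta_c, delta_u, delta_v).

    delta_u is NaN in partial contexts (the outcome is unobserved);
    delta_v is NaN for the non-relative families.
    """
    complete = context_information(context) == "complete"
    if complete and r_unchosen is None:
        raise ValueError("complete-information trial lacks the unchosen outcome")
    if not complete and r_unchosen is not None:
        raise ValueError("partial-information trial carries an unchosen outcome")
    v = state.V[context] if spec.relative else 0.0
    delta_c = r_chosen - v - state.Q[(context, chosen_good)]
    delta_u = (
        r_unchosen - v - state.Q[(context, not chosen_good)] if complete else MISSING
    )
    if spec.relative:
        other = (
            r_unchosen
            if complete
            else counterfactual_x(spec, params, state, context, chosen_good, r_chosen)
        )
        delta_v = (r_chosen + other) / 2.0 - state.V[context]
    else:
        delta_v = MISSING
    return delta_c, delta_u, delta_v


def _rate(spec: ModelSpec, params: dict[str, float], delta: float, chosen: bool) -> float:
    if not spec.asymmetric:
        return params["alpha_c"] if chosen else params["alpha_u"]
    confirming = delta > 0 if chosen else delta < 0
    return params["alpha_con"] if confirming else params["alpha_dis"]


def apply_update(
    spec: ModelSpec,
    params: dict[str, float],
    state: LearnerState,
    context: str,
    chosen_good: bool,
    r_chosen: float,
    r_unchosen: float | None,
    deltas: tuple[float, float, float],
) -> LearnerState:
    """Return the post-trial learner state (the input state is not mutated)."""
    delta_c, delta_u, delta_v = deltas
    new = state.copy()
    new.Q[(context, chosen_good)] += _rate(spec, params, delta_c, True) * delta_c
    if not math.isnan(delta_u):
        new.Q[(context, not chosen_good)] += (
            _rate(spec, params, delta_u, False) * delta_u
        )
    if spec.relative:
        new.V[context] += params["alpha_v"] * delta_v
    # refresh the per-symbol store of displayed outcomes
    new.last_outcome[(context, chosen_good)] = r_chosen
    if r_unchosen is not None:
        new.last_outcome[(context, not chosen_good)] = r_unchosen
    return new


_P_CLIP = 1e-12


def choice_prob_learning(q_a: float, q_b: float, beta: float) -> float:
    """Softmax probability of choosing option A over B."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    p = 1.0 / (1.0 + math.exp(-np.clip(beta * (q_a - q_b), -700, 700)))
    return min(max(p, _P_CLIP), 1.0 - _P_CLIP)


def choice_prob_transfer(q_end_c: float, q_end_d: float, beta: float) -> float:
    """Transfer-phase softmax on frozen end-of-learning Q values."""
    return choice_prob_learning(q_end_c, q_end_d, beta)


LATENT_COLUMNS = ["Qc", "Qu", "V", "delta_c", "delta_u", "delta_v", "choice_prob"]


def _check_learning_order(trials: pd.DataFrame) -> pd.DataFrame:
    learning = trials[trials["phase"] == "learning"]
    if learning.empty:
        raise ValueError("dataset has no learning trials")
    order = learning.sort_values(["run", "trial"], kind="stable")
    if not (order.index == learning.index).all():
        raise ValueError("learning trials must be ordered by run then trial")
    return learning


def run_model(
    spec: ModelSpec | str,
    params: dict[str, float],
    trials: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Filter one subject's trials through a model; return latents and the
    total choice log-likelihood (learning softmax + transfer softmax on
    frozen end-of-learning values).

    The latents (Qc, Qu, V, prediction errors, choice probability) are the
    pre-update quantities of each trial, aligned with the input rows.
    """
    from ._pack import pack_learning, pack_transfer
    from ._kernels import learning_pass

    spec = get_model(spec)
    validate_params(spec, params)
    learning = _check_learning_order(trials)
    packed = pack_learning(learning)
    theta = _theta_array(spec, params)
    latents, q_end, v_end, loglik = learning_pass(
        _FAMILY_CODE[spec.family],
        -1 if spec.counterfactual_variant is None
        else _VARIANT_CODE[spec.counterfactual_variant],
        theta, *packed,
    )
    lat = pd.DataFrame(latents, columns=LATENT_COLUMNS, index=learning.index)

    transfer = trials[trials["phase"] == "transfer"]
    if not transfer.empty:
        c_ctx, c_good, u_ctx, u_good = pack_transfer(transfer)
        qc = q_end[c_ctx, c_good]
        qu = q_end[u_ctx, u_good]
        p = 1.0 / (1.0 + np.exp(-np.clip(params["beta"] * (qc - qu), -700, 700)))
        p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
        loglik += float(np.log(p).sum())
        vt = (v_end[c_ctx] + v_end[u_ctx]) / 2.0
        tlat = pd.DataFrame(
            {
                "Qc": qc, "Qu": qu, "V": vt,
                "delta_c": np.nan, "delta_u": np.nan, "delta_v": np.nan,
                "choice_prob": p,
            },
            index=transfer.index,
        )
        lat = pd.concat([lat, tlat]).loc[trials.index]
    latents_df = lat
    latents_df.attrs["q_end"] = q_end
    latents_df.attrs["v_end"] = v_end
    return latents_df, float(loglik)


def _theta_array(spec: ModelSpec, params: dict[str, float]) -> np.ndarray:
    """(a1, a2, alpha_v, w, beta) with zeros for absent parameters."""
    if spec.asymmetric:
        a1, a2 = params["alpha_con"], params["alpha_dis"]
    else:
        a1, a2 = params["alpha_c"], params["alpha_u"]
    return np.array(
        [
            a1,
            a2,
            params.get("alpha_v", 0.0),
            params.get("w", 0.0),
            params["beta"],
        ]
    )


def params_from_vector(spec: ModelSpec, theta: np.ndarray) -> dict[str, float]:
    return dict(zip(spec.param_names, np.asarray(theta, dtype=float)))


def end_values(latents: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(Q_end, V_end) arrays stored by :func:`run_model` on its output."""
    return latents.attrs["q_end"], latents.attrs["v_end"]
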