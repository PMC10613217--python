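"""Synthetic agents: generative composition of the RL and confidence models.

An agent carries one RL model with parameters and one confidence model with
coefficients plus logit-scale report noise.  Simulated choices are sampled
from the agent's own running softmax; confidence is the inverse logit of
the linear predictor plus Gaussian noise, rounded to the 5% reporting grid.
Reaction times are not modeled and are recorded as missing.

The default cohort emulates the study conditions: 40 agents, 3 runs of 80
learning trials plus a 28-pair transfer phase, generated by the winning
model combination (relative-asymmetric learning with the weighted imaginary
counterfactual, and chosen-value-biased confidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .models import LearnerState, ModelSpec, get_model, validate_params
from .task import (
    TaskConfig,
    build_learning_design,
    build_transfer_design,
    draw_outcome_pair,
    expected_value,
    parse_symbol,
    symbol_id,
)

CONF_BIASES = ("none", "sumq", "qc", "v")

#: previous-confidence stand-in at each session's first trial (scale midpoint)
CONF_PREV_INIT = 0.75


@dataclass
class ConfParams:
    """Coefficients of the confidence regression (logit scale)."""

    b0: float = 0.0
    b_dq: float = 0.0
    b_bias: float = 0.0
    b_prev: float = 0.0


@dataclass
class AgentSpec:
    """Generative description of one synthetic participant."""

    model: str | ModelSpec = "relasym-imag"
    params: dict[str, float] = field(default_factory=dict)
    conf_bias: str = "qc"
    conf_params: ConfParams = field(default_factory=ConfParams)
    conf_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        spec = get_model(self.model)
        validate_params(spec, self.params)
        if self.conf_bias not in CONF_BIASES:
            raise ValueError(f"conf_bias must be one of {CONF_BIASES}")
        if self.conf_noise_sd < 0:
            raise ValueError("conf_noise_sd must be >= 0")


def _bias_value(bias: str, qc: float, qu: float, v: float) -> float:
    if bias == "none":
        return 0.0
    if bias == "sumq":
        return qc + qu
    if bias == "qc":
        return qc
    return v


def _round_to_grid(y: float) -> float:
    """Nearest 5% grid point in [0.5, 1]; ties round up."""
    idx = math.floor((y - 0.5) / 0.05 + 0.5 + 1e-12)
    return 0.5 + 0.05 * min(max(idx, 0), 10)


def _confidence(
    agent: AgentSpec,
    qc: float,
    qu: float,
    v: float,
    conf_prev: float | None,
    rng: np.random.Generator,
) -> float:
    cp = agent.conf_params
    lin = (
        cp.b0
        + cp.b_dq * abs(qc - qu)
        + cp.b_bias * _bias_value(agent.conf_bias, qc, qu, v)
    )
    if conf_prev is not None:
        lin += cp.b_prev * conf_prev
    if agent.conf_noise_sd > 0:
        lin += rng.normal(0.0, agent.conf_noise_sd)
    return _round_to_grid(1.0 / (1.0 + math.exp(-lin)))


def simulate_agent(
    agent: AgentSpec,
    config: TaskConfig,
    subject: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one agent through learning and transfer.

    Returns the trial table (canonical schema columns) augmented with the
    agent's own latent trajectories (Qc, Qu, V, prediction errors, choice
    probability of the chosen option).
    """
    spec = get_model(agent.model)
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed if seed is None else seed, subject))
    )
    design = build_learning_design(config, subject)
    state = LearnerState()
    rows = []
    conf_prev = CONF_PREV_INIT
    current_run = None
    for rec in design.itertuples(index=False):
        if rec.run != current_run:
            current_run = rec.run
            conf_prev = CONF_PREV_INIT
        context = rec.context
        outcome_good, outcome_bad = draw_outcome_pair(rec.valence, config, rng)
        p_good = models.choice_prob_learning(
            state.Q[(context, True)], state.Q[(context, False)],
            agent.params["beta"],
        )
        chosen_good = bool(rng.random() < p_good)
        r_chosen = outcome_good if chosen_good else outcome_bad
        complete = rec.information == "complete"
        r_unchosen = (outcome_bad if chosen_good else outcome_good) if complete else None

        qc = state.Q[(context, chosen_good)]
        qu = state.Q[(context, not chosen_good)]
        v = state.V[context]
        deltas = models.prediction_errors(
            spec, agent.params, state, context, chosen_good, r_chosen, r_unchosen
        )
        confidence = _confidence(agent, qc, qu, v, conf_prev, rng)
        rows.append(
            {
                "subject": subject,
                "run": rec.run,
                "trial": rec.trial,
                "context": context,
                "valence": rec.valence,
                "information": rec.information,
                "chosen": symbol_id(context, chosen_good),
                "correct": int(chosen_good),
                "outcome_chosen": r_chosen,
                "outcome_unchosen": np.nan if r_unchosen is None else r_unchosen,
                "confidence": confidence,
                "rt": np.nan,
                "phase": "learning",
                "Qc": qc,
                "Qu": qu,
                "V": v,
                "delta_c": deltas[0],
                "delta_u": deltas[1],
                "delta_v": deltas[2],
                "choice_prob": p_good if chosen_good else 1.0 - p_good,
            }
        )
        state = models.apply_update(
            spec, agent.params, state, context, chosen_good, r_chosen, r_unchosen, deltas
        )
        conf_prev = confidence

    # transfer: frozen end-of-learning values, shuffled pair order, no feedback
    pairs = build_transfer_design(config.symbols())
    order = rng.permutation(len(pairs))
    for trial, i in enumerate(order, start=1):
        a, b = pairs.iloc[i]["symbol_a"], pairs.iloc[i]["symbol_b"]
        qa = state.Q[parse_symbol(a)]
        qb = state.Q[parse_symbol(b)]
        p_a = models.choice_prob_transfer(qa, qb, agent.params["beta"])
        chose_a = bool(rng.random() < p_a)
        chosen, unchosen = (a, b) if chose_a else (b, a)
        qc, qu = (qa, qb) if chose_a else (qb, qa)
        v = (state.V[parse_symbol(a)[0]] + state.V[parse_symbol(b)[0]]) / 2.0
        ev_c = expected_value(chosen, config)
        ev_u = expected_value(unchosen, config)
        rows.append(
            {
                "subject": subject,
                "run": 1,
                "trial": trial,
                "context": f"{a}|{b}",
                "valence": np.nan,
                "information": np.nan,
                "chosen": chosen,
                "correct": np.nan if ev_c == ev_u else int(ev_c > ev_u),
                "outcome_chosen": np.nan,
                "outcome_unchosen": np.nan,
                "confidence": _confidence(agent, qc, qu, v, None, rng),
                "rt": np.nan,
                "phase": "transfer",
                "Qc": qc,
                "Qu": qu,
                "V": v,
                "delta_c": np.nan,
                "delta_u": np.nan,
                "delta_v": np.nan,
                "choice_prob": p_a if chose_a else 1.0 - p_a,
            }
        )
    return pd.DataFrame(rows)


# -- default cohort -----------------------------------------------------------

#: population-level generative parameters of the default cohort: moderate
#: confirmatory asymmetry, slow context-value learning (which leaves a
#: transient valence signature in the Q values), and a positive
#: chosen-value confidence bias.
DEFAULT_RL_MEANS = {
    "alpha_con": 0.35,
    "alpha_dis": 0.12,
    "alpha_v": 0.25,
    "w": 0.35,
    "beta": 5.0,
}
DEFAULT_CONF_PARAMS = ConfParams(b0=-0.6, b_dq=2.0, b_bias=1.5, b_prev=1.2)
DEFAULT_CONF_NOISE_SD = 0.5


def default_population(n_agents: int, rng: np.random.Generator) -> list[AgentSpec]:
    """Draw a cohort of agents around the default generative parameters.

    Learning rates and the counterfactual weight get additive Gaussian
    jitter (sd 0.05, clipped to the open unit interval); beta is jittered
    multiplicatively (lognormal sd 0.2); confidence coefficients get 10%
    relative jitter.
    """
    agents = []
    for _ in range(n_agents):
        params = {}
        for name, mean in DEFAULT_RL_MEANS.items():
            if name == "beta":
                params[name] = mean * rng.lognormal(0.0, 0.2)
            else:
                params[name] = float(np.clip(rng.normal(mean, 0.05), 0.01, 0.99))
        cp = DEFAULT_CONF_PARAMS
        conf = ConfParams(
            b0=cp.b0 * rng.lognormal(0.0, 0.1),
            b_dq=cp.b_dq * rng.lognormal(0.0, 0.1),
            b_bias=cp.b_bias * rng.lognormal(0.0, 0.1),
            b_prev=cp.b_prev * rng.lognormal(0.0, 0.1),
        )
        agents.append(
            AgentSpec(
                model="relasym-imag",
                params=params,
                conf_bias="qc",
                conf_params=conf,
                conf_noise_sd=DEFAULT_CONF_NOISE_SD,
            )
        )
    return agents


def simulate_cohort(
    config: TaskConfig | None = None,
    agents: list[AgentSpec] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a full cohort; defaults reproduce the study conditions."""
    config = config or TaskConfig()
    master = config.seed if seed is None else seed
    if agents is None:
        rng = np.random.default_rng(np.random.SeedSequence((master, 1_000_003)))
        agents = default_population(config.n_subjects, rng)
    frames = [
        simulate_agent(agent, config, subject=i, seed=master)
        for i, agent in enumerate(agents)
    ]
    return pd.concat(frames, ignore_index=True)
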