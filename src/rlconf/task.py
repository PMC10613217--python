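"""Two-armed bandit task with valence and information manipulations.

The learning task presents four fixed pairs of symbols (contexts), crossing
outcome valence (gain vs loss) with outcome information (partial vs complete
feedback).  Each symbol yields one of two magnitudes with reciprocal 75%/25%
probabilities; the symbol with the higher expected value is the "correct"
option.  After learning, a transfer phase pairs every symbol with every
other one (28 pairs) without feedback.  Confidence reports on a 50-100%
grid are incentivized with a matching-probability (reservation-lottery)
mechanism which makes truthful probability reporting payout-optimal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical context labels: Gain/Loss x Partial/Complete
CONTEXTS = ("GP", "LP", "GC", "LC")

#: columns of the canonical trial table (the CSV schema)
TRIAL_COLUMNS = [
    "subject", "run", "trial", "context", "valence", "information",
    "chosen", "correct", "outcome_chosen", "outcome_unchosen",
    "confidence", "rt", "phase",
]


def context_valence(context: str) -> str:
    return "gain" if context[0] == "G" else "loss"


def context_information(context: str) -> str:
    return "partial" if context[1] == "P" else "complete"


def symbol_id(context: str, good: bool) -> str:
    """Symbol ids encode their source context and expected-value rank."""
    return f"{context}_hi" if good else f"{context}_lo"


def parse_symbol(symbol: str) -> tuple[str, bool]:
    context, rank = symbol.split("_")
    return context, rank == "hi"


@dataclass
class TaskConfig:
    """Design parameters of the learning + transfer experiment.

    Defaults reproduce the study conditions: 40 subjects, 3 runs of 80
    trials (20 per context per run), 75/25 outcome probabilities with
    magnitudes +-1.0 / +-0.1 euro, confidence on a 50-100% grid in 5%
    steps, and a 5 euro confidence bonus.
    """

    n_subjects: int = 40
    n_runs: int = 3
    trials_per_context_per_run: int = 20
    contexts: tuple[str, ...] = CONTEXTS
    p_good: float = 0.75
    gain_magnitudes: tuple[float, float] = (1.0, 0.1)
    loss_magnitudes: tuple[float, float] = (-1.0, -0.1)
    confidence_grid: tuple[float, ...] = tuple(
        np.round(np.arange(0.50, 1.0001, 0.05), 2)
    )
    bonus_amount: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_runs < 1:
            raise ValueError("n_subjects and n_runs must be positive")
        if self.trials_per_context_per_run < 1:
            raise ValueError("trials_per_context_per_run must be positive")
        if not 0.5 < self.p_good <= 1.0:
            raise ValueError("p_good must lie in (0.5, 1]")
        if len(set(self.contexts)) != 4:
            raise ValueError("exactly four distinct contexts are required")
        if not all(m > 0 for m in self.gain_magnitudes):
            raise ValueError("gain magnitudes must share a positive sign")
        if not all(m < 0 for m in self.loss_magnitudes):
            raise ValueError("loss magnitudes must share a negative sign")
        grid = np.asarray(self.confidence_grid)
        if not (
            np.isclose(grid[0], 0.5)
            and np.isclose(grid[-1], 1.0)
            and np.allclose(np.diff(grid), 0.05)
        ):
            raise ValueError("confidence grid must span [0.5, 1] in 0.05 steps")

    def magnitudes(self, valence: str) -> tuple[float, float]:
        return self.gain_magnitudes if valence == "gain" else self.loss_magnitudes

    def symbols(self) -> list[str]:
        """The eight symbols of the design, two per context."""
        return [symbol_id(c, g) for c in self.contexts for g in (True, False)]


def _design_rng(master_seed: int, subject: int, run: int) -> np.random.Generator:
    # per-(subject, run) stream so designs are reproducible and independent
    return np.random.default_rng(np.random.SeedSequence((master_seed, subject, run)))


def build_learning_design(config: TaskConfig, subject: int) -> pd.DataFrame:
    """Trial shells for one subject: contexts interleaved uniformly per run.

    Returns a DataFrame of ``n_runs * 4 * trials_per_context_per_run`` rows
    with context/valence/information filled in and outcome fields empty.
    """
    config.validate()
    rows = []
    for run in range(1, config.n_runs + 1):
        labels = np.repeat(config.contexts, config.trials_per_context_per_run)
        rng = _design_rng(config.seed, subject, run)
        labels = rng.permutation(labels)
        for trial, context in enumerate(labels, start=1):
            rows.append(
                {
                    "subject": subject,
                    "run": run,
                    "trial": trial,
                    "context": context,
                    "valence": context_valence(context),
                    "information": context_information(context),
                    "phase": "learning",
                }
            )
    return pd.DataFrame(rows)


def draw_outcome_pair(
    valence: str, config: TaskConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw this trial's outcomes for the good and the bad option.

    Each option's outcome is drawn independently: the good option yields the
    better magnitude of its valence with probability ``p_good``, the bad
    option with probability ``1 - p_good``.  Both outcomes are always drawn;
    whether the unchosen one is *displayed* is the information manipulation,
    handled downstream.
    """
    mags = config.magnitudes(valence)
    better, worse = max(mags), min(mags)
    outcome_good = better if rng.random() < config.p_good else worse
    outcome_bad = better if rng.random() < 1.0 - config.p_good else worse
    return outcome_good, outcome_bad


def build_transfer_design(symbols: list[str]) -> pd.DataFrame:
    """All C(8,2)=28 unordered symbol pairs; original pairs flagged.

    A pair is "original" when both symbols come from the same learning
    context (4 such pairs).
    """
    if len(symbols) != 8 or len(set(symbols)) != 8:
        raise ValueError("transfer design requires exactly 8 distinct symbols")
    rows = []
    for a, b in itertools.combinations(symbols, 2):
        rows.append(
            {
                "symbol_a": a,
                "symbol_b": b,
                "original": parse_symbol(a)[0] == parse_symbol(b)[0],
            }
        )
    return pd.DataFrame(rows)


def expected_value(symbol: str, config: TaskConfig) -> float:
    """True expected outcome of a symbol under the task contingencies."""
    context, good = parse_symbol(symbol)
    mags = config.magnitudes(context_valence(context))
    better, worse = max(mags), min(mags)
    p = config.p_good if good else 1.0 - config.p_good
    return p * better + (1.0 - p) * worse


def matching_probability_bonus(
    p: float,
    correct: int,
    r: float,
    rng: np.random.Generator,
    bonus: float = 5.0,
) -> float:
    """Payout of the matching-probability confidence incentive.

    The reported confidence ``p`` is compared with a random lottery number
    ``r``: if ``p >= r`` the bonus is paid iff the choice was correct;
    otherwise the bonus is paid with probability ``r``.
    """
    if not 0.5 <= p <= 1.0 or not 0.5 <= r <= 1.0:
        raise ValueError("p and r must lie in [0.5, 1]")
    if correct not in (0, 1):
        raise ValueError("correct must be 0 or 1")
    if p >= r:
        return bonus * correct
    return bonus if rng.random() < r else 0.0


def expected_bonus(p: float, q: float, bonus: float = 5.0) -> float:
    """Expected matching-probability payout of reporting ``p`` when the
    subjective probability of being correct is ``q``, with the lottery
    number r ~ Uniform[0.5, 1].

    Integrating the payout rule over r gives
    ``bonus * (2 q (p - 1/2) + (1 - p^2))``, which is maximized at p = q —
    the mechanism is incentive compatible.
    """
    if not 0.5 <= p <= 1.0 or not 0.0 <= q <= 1.0:
        raise ValueError("p must lie in [0.5, 1] and q in [0, 1]")
    return bonus * (2.0 * q * (p - 0.5) + (1.0 - p * p))
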