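"""Array packing of trial tables for the fast likelihood kernel."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import CONTEXTS, parse_symbol

_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS)}


def pack_learning(learning: pd.DataFrame):
    """(ctx, chosen_good, complete, r_chosen, r_unchosen) int/float arrays.

    ``chosen_good`` is recovered from the ``correct`` column (the correct
    option is by definition the higher-expected-value symbol of the pair).
    """
    try:
        ctx = learning["context"].map(_CTX_INDEX).to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as err:
        raise ValueError("malformed context labels in learning trials") from err
    if learning["correct"].isna().any():
        raise ValueError("learning trials require the correct column")
    chosen_good = learning["correct"].to_numpy(dtype=np.int64)
    complete = (learning["information"] == "complete").to_numpy(dtype=np.int64)
    r_c = learning["outcome_chosen"].to_numpy(dtype=np.float64)
    r_u = learning["outcome_unchosen"].to_numpy(dtype=np.float64)
    if np.isnan(r_c).any():
        raise ValueError("learning trials require the chosen outcome")
    if (np.isnan(r_u) != (complete == 0)).any():
        raise ValueError(
            "outcome_unchosen must be present iff information is complete"
        )
    return ctx, chosen_good, complete, r_c, r_u


def pack_transfer(transfer: pd.DataFrame):
    """Chosen/unchosen (context index, rank) arrays for transfer trials.

    Transfer rows encode the pair in the context column as ``symA|symB``
    and the chosen symbol id in the chosen column.
    """
    c_ctx, c_good, u_ctx, u_good = [], [], [], []
    for pair, chosen in zip(transfer["context"], transfer["chosen"]):
        a, b = str(pair).split("|")
        if chosen not in (a, b):
            raise ValueError(f"chosen symbol {chosen!r} not in pair {pair!r}")
        unchosen = b if chosen == a else a
        ctx, good = parse_symbol(chosen)
        c_ctx.append(_CTX_INDEX[ctx])
        c_good.append(int(good))
        ctx, good = parse_symbol(unchosen)
        u_ctx.append(_CTX_INDEX[ctx])
        u_good.append(int(good))
    return (
        np.asarray(c_ctx, dtype=np.int64),
        np.asarray(c_good, dtype=np.int64),
        np.asarray(u_ctx, dtype=np.int64),
        np.asarray(u_good, dtype=np.int64),
    )
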