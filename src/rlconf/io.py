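"""Reading and writing the delimited-text interchange formats.

The trial table is UTF-8 CSV with one header row and the columns
``subject, run, trial, context, valence, information, chosen, correct,
outcome_chosen, outcome_unchosen, confidence, rt, phase``; missing values
are empty fields, confidence is stored as a proportion.  Transfer rows
encode the symbol pair in the context column (``symA|symB``).  Evidence
matrices are CSV with a model-label header row and one row per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import TRIAL_COLUMNS

_STRING_COLUMNS = ["context", "valence", "information", "chosen", "phase"]
_INT_COLUMNS = ["subject", "run", "trial"]
_FLOAT_COLUMNS = ["correct", "outcome_chosen", "outcome_unchosen", "confidence", "rt"]


def write_trials(trials: pd.DataFrame, path, include_latents: bool = False) -> None:
    columns = list(TRIAL_COLUMNS)
    if include_latents:
        columns += [c for c in trials.columns if c not in columns]
    trials[columns].to_csv(path, index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in _STRING_COLUMNS},
        float_precision="round_trip",
    )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    for col in _INT_COLUMNS:
        df[col] = df[col].astype(np.int64)
    for col in _FLOAT_COLUMNS:
        df[col] = df[col].astype(np.float64)
    for col in _STRING_COLUMNS:
        df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    return df


def validate_trials(trials: pd.DataFrame) -> None:
    """Schema checks on a trial table (raises on violation)."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    learning = trials[trials["phase"] == "learning"]
    partial = learning["information"] == "partial"
    if learning.loc[partial, "outcome_unchosen"].notna().any():
        raise ValueError("partial-information trials must hide outcome_unchosen")
    if learning.loc[~partial, "outcome_unchosen"].isna().any():
        raise ValueError("complete-information trials must show outcome_unchosen")
    conf = trials["confidence"].dropna()
    on_grid = np.isclose(np.round((conf - 0.5) / 0.05) * 0.05 + 0.5, conf)
    if not on_grid.all() or (conf < 0.5).any() or (conf > 1.0).any():
        raise ValueError("confidence ratings must lie on the 5% grid in [0.5, 1]")


def write_evidence(evidence: pd.DataFrame, path) -> None:
    evidence.to_csv(path, index=True, index_label="subject")


def read_evidence(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")
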