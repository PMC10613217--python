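"""Behavioral statistics: condition summaries, calibration, 2x2
repeated-measures ANOVA, t-tests, and robust inter-individual regression.

Accuracy is the probability of choosing the option with the higher expected
value; calibration is mean confidence minus mean accuracy (positive =
overconfident).  The 2x2 within-subject ANOVA is computed through
orthogonal paired contrasts — exact for single-degree-of-freedom effects,
where each effect's F equals the square of the corresponding paired t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .task import CONTEXTS


def condition_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-context means of accuracy, confidence, calibration
    and (when recorded) reaction time.  Learning-phase trials only."""
    learning = trials[trials["phase"] == "learning"]
    if learning.empty:
        raise ValueError("no learning-phase trials")
    grouped = learning.groupby(["subject", "context"], sort=True)
    out = grouped.agg(
        accuracy=("correct", "mean"),
        confidence=("confidence", "mean"),
        rt=("rt", "mean"),
    ).reset_index()
    out["calibration"] = out["confidence"] - out["accuracy"]
    return out[["subject", "context", "accuracy", "confidence", "calibration", "rt"]]


def to_condition_matrix(summary: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Subjects x 4-condition wide matrix for one measure."""
    wide = summary.pivot(index="subject", columns="context", values=measure)
    missing = set(CONTEXTS) - set(wide.columns)
    if missing or wide.isna().any().any():
        raise ValueError(f"incomplete condition data (missing {sorted(missing)})")
    return wide[list(CONTEXTS)]


def rm_anova_2x2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on a subjects x {GP, LP, GC, LC}
    matrix, via orthogonal paired contrasts.

    Returns one row per effect (valence, information, interaction) with
    F, df (1, n-1) and the two-sided p value.
    """
    m = to_condition_matrix_like(matrix)
    gp, lp, gc, lc = (m[c].to_numpy(dtype=float) for c in CONTEXTS)
    n = len(m)
    if n < 2:
        raise ValueError("at least two subjects are required")
    contrasts = {
        "valence": (gp + gc) / 2.0 - (lp + lc) / 2.0,
        "information": (gp + lp) / 2.0 - (gc + lc) / 2.0,
        "interaction": (gp - lp) - (gc - lc),
    }
    rows = []
    for effect, c in contrasts.items():
        t, df, p = ttests(c, popmean=0.0)
        rows.append(
            {"effect": effect, "F": t * t, "df1": 1, "df2": df, "p": p}
        )
    return pd.DataFrame(rows)


def to_condition_matrix_like(matrix: pd.DataFrame) -> pd.DataFrame:
    missing = set(CONTEXTS) - set(matrix.columns)
    if missing:
        raise ValueError(f"condition matrix lacks columns {sorted(missing)}")
    if matrix[list(CONTEXTS)].isna().any().any():
        raise ValueError("condition matrix has missing cells")
    return matrix[list(CONTEXTS)]


def ttests(
    x,
    y=None,
    popmean: float | None = None,
    paired: bool = True,
) -> tuple[float, int, float]:
    """One-sample (against ``popmean``) or paired t-test; returns
    (t, df, two-sided p).  A zero-variance sample is a contract violation
    (the statistic is undefined) and raises."""
    x = np.asarray(x, dtype=float)
    if y is not None:
        if not paired:
            raise ValueError("only paired two-sample comparisons are supported")
        x = x - np.asarray(y, dtype=float)
        popmean = 0.0
    if popmean is None:
        raise ValueError("provide either y or popmean")
    if len(x) < 2:
        raise ValueError("at least two observations are required")
    if np.std(x, ddof=1) == 0.0:
        raise ValueError("zero-variance sample: t statistic undefined")
    res = sps.ttest_1samp(x, popmean)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def robust_regression(x, y, tuning: float = 4.685):
    """Bisquare IRLS line fit y ~ a + b x (the same reweighting core as the
    confidence fits); returns a dict with slope/intercept, their standard
    errors, and two-sided p values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("at least three points are required")
    design = sm.add_constant(x)
    res = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=tuning)).fit(
        conv="coefs", tol=1e-8
    )
    z = res.params / res.bse
    p = 2.0 * sps.norm.sf(np.abs(z))
    return {
        "intercept": float(res.params[0]),
        "slope": float(res.params[1]),
        "intercept_se": float(res.bse[0]),
        "slope_se": float(res.bse[1]),
        "intercept_p": float(p[0]),
        "slope_p": float(p[1]),
    }
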