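"""Orchestration: simulate -> fit RL -> fit confidence -> BMS -> stats ->
regressor export, with seeds and checksums recorded in a run manifest."""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .bms import BayesianModelSelection
from .confidence import ConfSpec, build_predictors
from .fitting import ConfidenceRegression, RLModelMAP
from .models import MODEL_SPACE, run_model
from .simulate import simulate_cohort
from .stats import condition_summary, rm_anova_2x2, to_condition_matrix
from .task import TaskConfig

STAGES = ("simulate", "fit-rl", "fit-conf", "bms", "stats", "export-regressors")

REGRESSOR_COLUMNS = ["Qc", "Qu", "V", "dq_abs", "conf", "conf_prev", "pe"]


def export_regressors(table: pd.DataFrame) -> pd.DataFrame:
    """Session-wise z-scored parametric modulators.

    ``table`` must carry subject/run labels, latent columns (Qc, Qu, V,
    delta_c), and confidence.  Each exported column has mean 0 and sd 1
    within every subject x session; constant columns are emitted as zeros
    with a warning.
    """
    learning = table[table["phase"] == "learning"].copy()
    learning["dq_abs"] = (learning["Qc"] - learning["Qu"]).abs()
    learning["conf"] = learning["confidence"]
    learning["pe"] = learning["delta_c"]
    prev = learning.groupby(["subject", "run"])["confidence"].shift(1)
    learning["conf_prev"] = prev.fillna(0.75)

    def zscore(group: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in REGRESSOR_COLUMNS:
            x = group[col].to_numpy(dtype=float)
            sd = x.std()
            # constant up to summation rounding noise
            if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
                warnings.warn(
                    f"constant regressor {col!r} in subject "
                    f"{group.name[0]} run {group.name[1]}; emitting zeros",
                    stacklevel=2,
                )
                out[col] = np.zeros_like(x)
            else:
                out[col] = (x - x.mean()) / sd
        return pd.DataFrame(out, index=group.index)

    scored = learning.groupby(["subject", "run"], group_keys=False)[
        REGRESSOR_COLUMNS
    ].apply(zscore)
    result = learning[["subject", "run", "trial"]].join(scored)
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> TaskConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    tuples = {
        "contexts", "gain_magnitudes", "loss_magnitudes", "confidence_grid",
    }
    kwargs = {k: tuple(v) if k in tuples else v for k, v in raw.items()}
    return TaskConfig(**kwargs)


def run_pipeline(
    config: TaskConfig | None = None,
    stages: tuple[str, ...] = STAGES,
    out_dir: str | Path = "rlconf_out",
    seed: int | None = None,
    models: tuple[str, ...] = tuple(MODEL_SPACE),
    n_starts: int = 10,
    n_subjects: int | None = None,
) -> dict:
    """Run the requested stages in dependency order; returns the manifest.

    Later stages read the artifacts of earlier ones from ``out_dir``, so a
    stage whose inputs are absent raises a dependency error.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    config = config or TaskConfig()
    if seed is not None:
        config = TaskConfig(**{**config.__dict__, "seed": seed})
    if n_subjects is not None:
        config = TaskConfig(**{**config.__dict__, "n_subjects": n_subjects})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "master_seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in config.__dict__.items()},
        "stages": {},
    }

    def record(stage: str, paths: list[Path], **extra) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths},
            "timestamp": datetime.now(timezone.utc).isoformat(),
            **extra,
        }

    def require(path: Path, needed_by: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage {needed_by!r} requires missing upstream output {path}"
            )
        return path

    trials_path = out / "trials.csv"
    evidence_path = out / "rl_evidence.csv"
    fits_path = out / "rl_fits.json"
    latents_path = out / "latents.csv"

    if "simulate" in stages:
        trials = simulate_cohort(config)
        io.validate_trials(trials)
        io.write_trials(trials, trials_path, include_latents=True)
        record("simulate", [trials_path], seed=config.seed)

    if "fit-rl" in stages:
        trials = io.read_trials(require(trials_path, "fit-rl"))
        rows, fits = {}, {}
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 5)))
        for subject, sub in trials.groupby("subject"):
            seeds = {m: int(rng.integers(0, 2**31 - 1)) for m in models}
            rows[subject] = {}
            for m in models:
                fit = RLModelMAP(model=m, n_starts=n_starts,
                                 random_state=seeds[m]).fit(sub)
                rows[subject][m] = fit.log_evidence_
                fits[f"{subject}:{m}"] = {
                    "params": fit.params_,
                    "nlpp": fit.nlpp_,
                    "log_evidence": fit.log_evidence_,
                    "n_converged": fit.n_converged_,
                    "seed": seeds[m],
                }
        evidence = pd.DataFrame(rows).T.loc[:, list(models)]
        io.write_evidence(evidence, evidence_path)
        fits_path.write_text(json.dumps(fits, indent=1))
        record("fit-rl", [evidence_path, fits_path], models=list(models))

    if "bms" in stages:
        evidence = io.read_evidence(require(evidence_path, "bms"))
        bms = BayesianModelSelection(random_state=config.seed).fit(evidence)
        payload = {
            "models": bms.model_labels_,
            "alpha": bms.alpha_.tolist(),
            "ef": bms.ef_.tolist(),
            "ep": bms.ep_.tolist(),
            "bor": bms.bor_,
            "pep": bms.pep_.tolist(),
        }
        (out / "bms.json").write_text(json.dumps(payload, indent=1))
        record("bms", [out / "bms.json"])
        winner = bms.model_labels_[int(np.argmax(bms.ef_))]
        manifest["stages"]["bms"]["winner"] = winner

    if "fit-conf" in stages:
        trials = io.read_trials(require(trials_path, "fit-conf"))
        evidence = io.read_evidence(require(evidence_path, "fit-conf"))
        winner = evidence.sum(axis=0).idxmax()
        fits = json.loads(require(fits_path, "fit-conf").read_text())
        conf_rows = {}
        latent_frames = []
        for subject, sub in trials.groupby("subject"):
            params = fits[f"{subject}:{winner}"]["params"]
            latents, _ = run_model(winner, params, sub)
            learning = sub["phase"] == "learning"
            latent_frames.append(
                pd.concat([sub[["subject", "run", "trial", "phase"]], latents], axis=1)
            )
            conf_rows[subject] = {}
            for bias in ("none", "sumq", "qc", "v"):
                spec = ConfSpec(bias=bias, phase="learning")
                X = build_predictors(
                    latents[learning],
                    sub.loc[learning, "confidence"],
                    spec,
                    runs=sub.loc[learning, "run"],
                )
                fit = ConfidenceRegression(bias=bias, phase="learning").fit(
                    X, sub.loc[learning, "confidence"]
                )
                conf_rows[subject][bias] = -0.5 * fit.bic_
        conf_evidence = pd.DataFrame(conf_rows).T
        io.write_evidence(conf_evidence, out / "conf_evidence.csv")
        pd.concat(latent_frames).to_csv(latents_path, index=False)
        record("fit-conf", [out / "conf_evidence.csv", latents_path],
               rl_winner=str(winner))

    if "stats" in stages:
        trials = io.read_trials(require(trials_path, "stats"))
        summary = condition_summary(trials)
        summary.to_csv(out / "condition_summary.csv", index=False)
        tables = []
        for measure in ("accuracy", "confidence", "calibration"):
            anova = rm_anova_2x2(to_condition_matrix(summary, measure))
            anova.insert(0, "measure", measure)
            tables.append(anova)
        pd.concat(tables).to_csv(out / "anova.csv", index=False)
        record("stats", [out / "condition_summary.csv", out / "anova.csv"])

    if "export-regressors" in stages:
        trials = io.read_trials(require(trials_path, "export-regressors"))
        if "Qc" not in trials.columns:
            latents = pd.read_csv(require(latents_path, "export-regressors"))
            trials = trials.merge(latents, on=["subject", "run", "trial", "phase"])
        regressors = export_regressors(trials)
        regressors.to_csv(out / "regressors.csv", index=False)
        record("export-regressors", [out / "regressors.csv"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
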