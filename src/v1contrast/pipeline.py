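"""Stage orchestration: simulate -> tuning -> contrast models -> GLM -> SSN.

Every stage is a pure function of (tables, config, seed); the pipeline runs
the requested stages in order, writes delimited outputs plus a JSON
manifest, and is byte-reproducible under a fixed config and seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import crf, glm, io, ssn, synth, tuning

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "stages": ["simulate", "tuning", "contrast", "glm"],
    "seed": 0,
    "simulate": {
        "preset": "vip",
        "n_neurons": 50,
        "n_reps": 15,
        "n_blanks": 30,
        "n_sessions": 3,
        "run_prob": 0.4,
        "zero_prob": 0.15,
        "gamma_shape": 2.0,
    },
    "tuning": {"n_shuffles": 2000, "n_boot": 2000, "alpha": 0.01},
    "contrast": {"n_shuffles": 1000},
    "glm": {"n_lambdas": 16},
    "ssn": {
        "strengths": list(np.arange(0.0, 101.0, 10.0)),
        "directions": list(np.arange(0.0, 360.0, 45.0)),
    },
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def stage_simulate(config: dict, out_dir: Path) -> tuple[pd.DataFrame, np.ndarray]:
    p = config["simulate"]
    stim, truth, responses = synth.generate_dataset(
        p["preset"],
        p["n_neurons"],
        n_reps=p["n_reps"],
        n_blanks=p["n_blanks"],
        n_sessions=p["n_sessions"],
        noise=synth.NoiseSpec(p["zero_prob"], p["gamma_shape"]),
        seed=config["seed"],
        run_prob=p["run_prob"],
    )
    io.write_stimulus_table(stim, out_dir / "stimulus.csv")
    io.write_responses(responses, out_dir / "responses.csv")
    io.write_ground_truth(truth, out_dir / "ground_truth.csv")
    return stim, responses


def stage_tuning(stim: pd.DataFrame, responses: np.ndarray, config: dict, out_dir: Path):
    p = config["tuning"]
    metrics = tuning.compute_cell_metrics(
        responses,
        stim,
        n_shuffles=p["n_shuffles"],
        n_boot=p["n_boot"],
        alpha=p["alpha"],
        seed=config["seed"] + 1,
    )
    metrics.to_csv(out_dir / "cell_metrics.csv", index=False)
    split = tuning.split_by_locomotion(stim)
    summary = tuning.population_tuning_summary(
        responses, stim, split, responsive=metrics["responsive"].to_numpy()
    )
    summary["surface"].to_csv(out_dir / "population_summary.csv", index=False)
    return metrics


def stage_contrast(stim: pd.DataFrame, responses: np.ndarray, config: dict, out_dir: Path):
    codes = tuning.condition_codes(stim)
    rows = []
    rng = np.random.default_rng(config["seed"] + 2)
    for i, cell in enumerate(np.atleast_2d(responses)):
        cond_means = np.array(
            [
                cell[codes == d * len(synth.CONTRASTS) + c].mean()
                for d in range(len(synth.DIRECTIONS))
                for c in range(len(synth.CONTRASTS))
            ]
        ).reshape(len(synth.DIRECTIONS), len(synth.CONTRASTS))
        pref_d = int(np.argmax(cond_means.max(axis=1)))
        sel = np.isin(codes, pref_d * len(synth.CONTRASTS) + np.arange(len(synth.CONTRASTS)))
        choice = crf.select_contrast_model(
            stim["contrast"].to_numpy()[sel],
            cell[sel],
            n_shuffles=config["contrast"]["n_shuffles"],
            seed=rng,
        )
        rows.append(
            {
                "neuron_id": i,
                "model_class": choice.kind or "unclassified",
                **{f"aic_{k}": f.aic for k, f in choice.fits.items()},
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "contrast_models.csv", index=False)
    return table


def stage_glm(stim: pd.DataFrame, responses: np.ndarray, config: dict, out_dir: Path):
    X, _ = glm.build_design_matrix(stim)
    y = np.atleast_2d(responses).mean(axis=0)
    sessions = stim["session_id"].to_numpy()
    if np.unique(sessions).size >= 2:
        lam, cv = glm.cross_validate_lambda(
            X, y, sessions, glm.lambda_grid(X, y, config["glm"]["n_lambdas"])
        )
        cv.to_csv(out_dir / "glm_cv.csv", index=False)
    else:
        lam = 0.0
    fit = glm.fit_l1(X, y, lam)
    glm.weight_table(fit).to_csv(out_dir / "glm_weights.csv", index=False)
    glm.prediction_surface(fit).to_csv(out_dir / "glm_predictions.csv", index=False)
    return fit


def stage_ssn(config: dict, out_dir: Path):
    p = config["ssn"]
    net = ssn.SSNetwork()
    surface = ssn.tuning_surface(net, p["directions"], p["strengths"])
    surface.to_csv(out_dir / "ssn_tuning_surface.csv", index=False)
    stability = ssn.stability_curve(net, p["strengths"])
    stability.to_csv(out_dir / "ssn_stability.csv", index=False)
    return surface, stability


def run_pipeline(config: dict | None = None, out_dir: str | Path = "outputs") -> dict:
    """Execute the configured stages and return the run manifest."""
    config = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {"config": config, "version": __version__, "stages": {}}
    stim = responses = None
    for stage in config["stages"]:
        t0 = time.perf_counter()
        logger.info("running stage %s", stage)
        if stage == "simulate":
            stim, responses = stage_simulate(config, out_dir)
        elif stage in ("tuning", "contrast", "glm"):
            if stim is None:
                stim, responses = io.load_tables(
                    out_dir / "stimulus.csv", out_dir / "responses.csv"
                )
            if stage == "tuning":
                stage_tuning(stim, responses, config, out_dir)
            elif stage == "contrast":
                stage_contrast(stim, responses, config, out_dir)
            else:
                stage_glm(stim, responses, config, out_dir)
        elif stage == "ssn":
            stage_ssn(config, out_dir)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
    manifest["checksums"] = {
        f.name: io.file_checksum(f) for f in sorted(out_dir.glob("*.csv"))
    }
    io.write_manifest(manifest, out_dir / "manifest.json")
    return manifest
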