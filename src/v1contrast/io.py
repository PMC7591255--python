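"""Table and configuration I/O with validation.

All interchange is plain delimited text (comma-separated, UTF-8, one header
row): stimulus tables and metric tables are written as-is; response
matrices are written with trials as rows and neurons as columns.  Run
configuration round-trips through YAML or JSON, and each pipeline run ends
with an atomically-written JSON manifest (config snapshot, package version,
stage timings, output checksums).
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

STIMULUS_COLUMNS = [
    "trial_id",
    "session_id",
    "direction",
    "contrast",
    "is_blank",
    "run_speed",
    "run_state",
]


class ValidationError(ValueError):
    """A loaded table violates the schema; the message names the offender."""


def write_stimulus_table(stimulus: pd.DataFrame, path: str | Path) -> None:
    stimulus.to_csv(path, index=False)


def read_stimulus_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STIMULUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing stimulus columns {missing}")
    df["is_blank"] = df["is_blank"].astype(bool)
    df["run_state"] = df["run_state"].astype(bool)
    blanks = df["is_blank"]
    bad = df.index[blanks & (df["contrast"] != 0)].tolist()
    if bad:
        raise ValidationError(f"{path}: blank rows with nonzero contrast at rows {bad[:5]}")
    bad = df.index[~blanks & df["direction"].isna()].tolist()
    if bad:
        raise ValidationError(f"{path}: grating rows without direction at rows {bad[:5]}")
    if (df["run_speed"] < 0).any():
        bad = df.index[df["run_speed"] < 0].tolist()
        raise ValidationError(f"{path}: negative run speeds at rows {bad[:5]}")
    return df


def write_responses(responses: np.ndarray, path: str | Path) -> None:
    """Write a (neurons x trials) matrix as trials-by-rows CSV."""
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    cols = [f"n{i:04d}" for i in range(responses.shape[0])]
    pd.DataFrame(responses.T, columns=cols).to_csv(path, index_label="trial")


def read_responses(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy(dtype=float).T
    if not np.all(np.isfinite(arr)):
        neuron, trial = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"{path}: non-finite response for neuron {df.columns[neuron]} trial {trial}"
        )
    if np.any(arr < 0):
        neuron, trial = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{path}: negative response for neuron {df.columns[neuron]} trial {trial}"
        )
    return arr


def load_tables(stimulus_path: str | Path, responses_path: str | Path):
    """Load and cross-validate a stimulus table and response matrix."""
    stimulus = read_stimulus_table(stimulus_path)
    responses = read_responses(responses_path)
    if responses.shape[1] != len(stimulus):
        raise ValidationError(
            f"trial-count mismatch: {responses.shape[1]} response columns vs "
            f"{len(stimulus)} stimulus rows"
        )
    return stimulus, responses


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    text = (
        json.dumps(config, indent=2, sort_keys=True)
        if path.suffix == ".json"
        else yaml.safe_dump(config, sort_keys=True)
    )
    path.write_text(text)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    return json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Atomic JSON write: temp file in the same directory, then rename."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    os.replace(tmp, path)
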