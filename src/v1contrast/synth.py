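"""Synthetic drifting-grating sessions with known ground-truth tuning.

The generator emulates the experimental design the statistical pipeline
assumes: 8 drifting-grating directions x 6 contrasts (5-80%), 15-24 repeats
per condition, randomly interleaved blank (mean-luminance) trials, and a
per-trial locomotion state.  Per-trial responses are mean calcium-event
magnitudes per second: sparse, nonnegative and overdispersed, modeled here
as zero-inflated gamma variates around a multiplicative mean model

    mu(trial) = baseline * run_gain^run * D(direction) * C(contrast)

with a von-Mises direction kernel ``D`` (peak 1 at the preferred direction)
and a sigmoidal contrast kernel ``C`` expressed relative to the blank
baseline.  Ground truth is returned alongside the data so that every
downstream estimator can be checked against what generated it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Grating drift directions in degrees (0 = horizontal front-to-back motion).
DIRECTIONS = np.arange(0.0, 360.0, 45.0)
#: Grating contrasts as fractions.
CONTRASTS = np.array([0.05, 0.10, 0.20, 0.40, 0.60, 0.80])
#: Locomotion threshold on mean trial running speed (cm/s).
RUN_SPEED_THRESHOLD = 1.0

#: Fixed slope of all contrast sigmoids (contrast handled as a fraction).
SIGMOID_SLOPE = 10.0

CONTRAST_CLASSES = ("low_pass", "high_pass", "band_pass", "flat", "suppressed")

PRESETS: dict[str, dict] = {
    # Nearly all VIP cells prefer low contrast and front-to-back motion
    # (0 degrees), with high spontaneous rates, strong locomotion gain and a
    # sub-baseline response at high contrast.
    "vip": {
        "mixture": {"low_pass": 0.95, "suppressed": 0.05},
        "direction": ("vonmises", 0.0, 10.0),
        "kappa": (1.0, 3.0),
        "run_gain": (1.5, 2.5),
        "baseline": (0.10, 0.30),
    },
    # SST cells prefer high contrast, are weakly direction selective and
    # tile direction preferences.
    "sst": {
        "mixture": {"high_pass": 1.0},
        "direction": ("tiled", None, None),
        "kappa": (0.1, 0.5),
        "run_gain": (1.2, 2.0),
        "baseline": (0.02, 0.10),
    },
    # Layer 2/3 pyramidal cells mix low- and high-contrast preference with
    # substantial, tiled direction selectivity.
    "cux2": {
        "mixture": {"low_pass": 0.50, "high_pass": 0.45, "flat": 0.05},
        "direction": ("tiled", None, None),
        "kappa": (0.5, 3.0),
        "run_gain": (1.2, 2.0),
        "baseline": (0.02, 0.10),
    },
    # Exchangeable null cells for calibration checks.
    "flat": {
        "mixture": {"flat": 1.0},
        "direction": ("tiled", None, None),
        "kappa": (0.0, 0.0),
        "run_gain": (1.0, 1.0),
        "baseline": (0.05, 0.20),
    },
}


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-inflated gamma trial noise.

    ``zero_prob`` is the probability of an eventless (zero) trial and
    ``shape`` the gamma shape of nonzero trials.  The gamma scale is chosen
    so the overall expectation equals the mean model.  ``shape=None``
    requests the deterministic (noise-free) limit.
    """

    zero_prob: float = 0.15
    shape: float | None = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_prob < 1.0:
            raise ValueError(f"zero_prob must be in [0, 1), got {self.zero_prob}")
        if self.shape is not None and not self.shape > 0:
            raise ValueError(f"shape must be positive or None, got {self.shape}")


def _rising(c: np.ndarray, c50: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-SIGMOID_SLOPE * (c - c50)))


def _falling(c: np.ndarray, c50: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(SIGMOID_SLOPE * (c - c50)))


def make_stimulus_table(
    n_reps: int = 15,
    n_blanks: int = 30,
    n_sessions: int = 1,
    seed: int | np.random.Generator = 0,
    run_prob: float = 0.4,
    speed_threshold: float = RUN_SPEED_THRESHOLD,
) -> pd.DataFrame:
    """Build a randomized trial table for one or more sessions.

    Each session presents all 48 (direction, contrast) conditions ``n_reps``
    times plus ``n_blanks`` interleaved blank trials, in random order.
    Running state is an i.i.d. Bernoulli(``run_prob``) per trial,
    independent of the stimulus; trial speeds are drawn above or below
    ``speed_threshold`` accordingly.
    """
    if not isinstance(n_reps, (int, np.integer)) or isinstance(n_reps, bool):
        raise TypeError(f"n_reps must be an integer, got {type(n_reps).__name__}")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if n_blanks < 0:
        raise ValueError(f"n_blanks must be >= 0, got {n_blanks}")
    if n_sessions < 1:
        raise ValueError(f"n_sessions must be >= 1, got {n_sessions}")
    rng = np.random.default_rng(seed)

    frames = []
    for session in range(n_sessions):
        dirs = np.repeat(np.tile(DIRECTIONS, len(CONTRASTS)), n_reps)
        cons = np.repeat(np.repeat(CONTRASTS, len(DIRECTIONS)), n_reps)
        direction = np.concatenate([dirs, np.full(n_blanks, np.nan)])
        contrast = np.concatenate([cons, np.zeros(n_blanks)])
        is_blank = np.concatenate(
            [np.zeros(dirs.size, dtype=bool), np.ones(n_blanks, dtype=bool)]
        )
        order = rng.permutation(direction.size)
        direction, contrast, is_blank = direction[order], contrast[order], is_blank[order]

        running = rng.random(direction.size) < run_prob
        speed = np.where(
            running,
            speed_threshold + rng.gamma(2.0, 3.0, size=direction.size),
            rng.uniform(0.0, speed_threshold, size=direction.size),
        )
        frames.append(
            pd.DataFrame(
                {
                    "session_id": session,
                    "direction": direction,
                    "contrast": contrast,
                    "is_blank": is_blank,
                    "run_speed": speed,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "trial_id", np.arange(len(table)))
    table["run_state"] = table["run_speed"] >= speed_threshold
    return table


def _sample_class_params(cls: str, rng: np.random.Generator) -> dict:
    """Contrast-kernel parameters (relative to baseline) for one neuron."""
    if cls == "flat":
        return {"b": 1.0, "h": 0.0, "c50r": np.nan, "c50f": np.nan}
    if cls == "low_pass":
        return {
            "b": rng.uniform(0.1, 0.4),
            "h": rng.uniform(2.5, 4.0),
            "c50r": np.nan,
            "c50f": rng.uniform(0.10, 0.25),
        }
    if cls == "high_pass":
        return {
            "b": rng.uniform(0.2, 0.5),
            "h": rng.uniform(2.5, 4.0),
            "c50r": rng.uniform(0.25, 0.50),
            "c50f": np.nan,
        }
    if cls == "band_pass":
        return {
            "b": rng.uniform(0.05, 0.2),
            "h": rng.uniform(4.0, 6.0),
            "c50r": rng.uniform(0.08, 0.15),
            "c50f": rng.uniform(0.30, 0.40),
        }
    if cls == "suppressed":
        # Falling kernel with floor below baseline: suppressed at 80%.
        return {
            "b": rng.uniform(0.1, 0.4),
            "h": rng.uniform(2.0, 3.5),
            "c50r": np.nan,
            "c50f": rng.uniform(0.10, 0.20),
        }
    raise ValueError(f"unknown contrast class {cls!r}")


def sample_population_tuning(
    population_spec: str | Mapping[str, float],
    n_neurons: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw per-neuron ground truth from a named preset or explicit mixture.

    Presets (``"vip"``, ``"sst"``, ``"cux2"``, ``"flat"``) encode the
    population phenomenology of the corresponding cell classes; an explicit
    mixture is a mapping from contrast class to proportion (summing to 1)
    and uses the ``"flat"`` preset's direction/gain/baseline settings except
    that direction preferences are tiled.
    """
    if n_neurons < 1:
        raise ValueError(f"n_neurons must be >= 1, got {n_neurons}")
    if isinstance(population_spec, str):
        if population_spec not in PRESETS:
            raise ValueError(
                f"unknown preset {population_spec!r}; options: {sorted(PRESETS)}"
            )
        preset = PRESETS[population_spec]
        mixture = preset["mixture"]
    else:
        mixture = dict(population_spec)
        unknown = set(mixture) - set(CONTRAST_CLASSES)
        if unknown:
            raise ValueError(f"unknown contrast classes in mixture: {sorted(unknown)}")
        if abs(sum(mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        preset = PRESETS["flat"] | {"mixture": mixture, "kappa": (0.5, 3.0)}
        if mixture != {"flat": 1.0}:
            preset = preset | {"run_gain": (1.2, 2.0)}

    rng = np.random.default_rng(seed)
    classes = list(mixture)
    probs = np.array([mixture[c] for c in classes], dtype=float)
    cls = rng.choice(classes, size=n_neurons, p=probs / probs.sum())

    dir_mode, dir_mu, dir_kappa = preset["direction"]
    if dir_mode == "vonmises":
        pref = np.degrees(rng.vonmises(np.radians(dir_mu), dir_kappa, size=n_neurons))
        pref %= 360.0
    else:  # tiled: uniform over the 8 stimulus directions
        pref = rng.choice(DIRECTIONS, size=n_neurons)

    rows = []
    for i in range(n_neurons):
        p = _sample_class_params(cls[i], rng)
        kappa = 0.0 if cls[i] == "flat" else rng.uniform(*preset["kappa"])
        run_gain = 1.0 if cls[i] == "flat" else rng.uniform(*preset["run_gain"])
        rows.append(
            {
                "neuron_id": i,
                "contrast_class": cls[i],
                "b": p["b"],
                "h": p["h"],
                "c50r": p["c50r"],
                "c50f": p["c50f"],
                "preferred_direction": 0.0 if cls[i] == "flat" else pref[i],
                "direction_concentration": kappa,
                "run_gain": run_gain,
                "baseline_rate": rng.uniform(*preset["baseline"]),
            }
        )
    return pd.DataFrame(rows)


def contrast_kernel(truth_row: Mapping, contrast: np.ndarray) -> np.ndarray:
    """Relative mean response versus contrast for one neuron (blank == 1)."""
    c = np.asarray(contrast, dtype=float)
    cls = truth_row["contrast_class"]
    b, h = truth_row["b"], truth_row["h"]
    if cls == "flat":
        return np.ones_like(c)
    if cls in ("low_pass", "suppressed"):
        return b + h * _falling(c, truth_row["c50f"])
    if cls == "high_pass":
        return b + h * _rising(c, truth_row["c50r"])
    if cls == "band_pass":
        return b + h * _rising(c, truth_row["c50r"]) * _falling(c, truth_row["c50f"])
    raise ValueError(f"unknown contrast class {cls!r}")


def direction_kernel(truth_row: Mapping, direction: np.ndarray) -> np.ndarray:
    """Von-Mises direction kernel on 360 degrees, peak 1 at the preference."""
    delta = np.radians(np.asarray(direction, dtype=float) - truth_row["preferred_direction"])
    return np.exp(truth_row["direction_concentration"] * (np.cos(delta) - 1.0))


def mean_response_model(truth: pd.DataFrame, stimulus: pd.DataFrame) -> np.ndarray:
    """Expected response per (neuron, trial) under the generative mean model."""
    n_trials = len(stimulus)
    blank = stimulus["is_blank"].to_numpy()
    run = stimulus["run_state"].to_numpy()
    direction = stimulus["direction"].to_numpy()
    contrast = stimulus["contrast"].to_numpy()

    mu = np.empty((len(truth), n_trials))
    for i, (_, row) in enumerate(truth.iterrows()):
        gain = np.where(run, row["run_gain"], 1.0)
        resp = np.ones(n_trials)
        grating = ~blank
        resp[grating] = contrast_kernel(row, contrast[grating]) * direction_kernel(
            row, direction[grating]
        )
        mu[i] = row["baseline_rate"] * gain * resp
    if np.any(mu < 0):
        logger.warning("negative mean responses requested; clipping to 0")
        mu = np.clip(mu, 0.0, None)
    return mu


def generate_event_responses(
    stimulus: pd.DataFrame,
    truth: pd.DataFrame,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a (neurons x trials) event-response matrix.

    Responses are zero-inflated gamma around the mean model, so that the
    expectation over repeats equals ``mean_response_model`` exactly.
    """
    rng = np.random.default_rng(seed)
    mu = mean_response_model(truth, stimulus)
    if noise.shape is None or np.isinf(noise.shape):
        return mu
    nonzero = rng.random(mu.shape) >= noise.zero_prob
    scale = mu / (noise.shape * (1.0 - noise.zero_prob))
    draws = rng.gamma(noise.shape, 1.0, size=mu.shape) * scale
    return np.where(nonzero, draws, 0.0)


def generate_dataset(
    population_spec: str | Mapping[str, float],
    n_neurons: int,
    n_reps: int = 15,
    n_blanks: int = 30,
    n_sessions: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    run_prob: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Convenience wrapper: (stimulus, ground truth, responses) in one call."""
    rng = np.random.default_rng(seed)
    stim = make_stimulus_table(
        n_reps=n_reps, n_blanks=n_blanks, n_sessions=n_sessions, seed=rng, run_prob=run_prob
    )
    truth = sample_population_tuning(population_spec, n_neurons, seed=rng)
    responses = generate_event_responses(stim, truth, noise=noise, seed=rng)
    return stim, truth, responses
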