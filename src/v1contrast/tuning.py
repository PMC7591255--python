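"""Per-cell and population tuning statistics for drifting-grating responses.

Implements the trial-wise statistical pipeline: the bootstrapped chi-square
responsiveness test, blank-subtracted condition response percentiles and the
suppressed-by-contrast classification, selectivity metrics (gOSI, DSI),
contrast preference (cCoM, the log-scaled center of mass of the contrast
response function), population direction bias with a uniform-null confidence
radius, response normalization, and locomotion-conditioned tuning summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import CONTRASTS, DIRECTIONS, RUN_SPEED_THRESHOLD

logger = logging.getLogger(__name__)

N_CONDITIONS = len(DIRECTIONS) * len(CONTRASTS) + 1  # 48 gratings + blank


class ConfigurationError(ValueError):
    """Raised when the stimulus table cannot support the requested analysis."""


def condition_codes(stimulus: pd.DataFrame) -> np.ndarray:
    """Integer condition code per trial: dir_idx * 6 + contrast_idx, blank = 48."""
    codes = np.full(len(stimulus), len(DIRECTIONS) * len(CONTRASTS), dtype=np.intp)
    grating = ~stimulus["is_blank"].to_numpy()
    d_idx = np.searchsorted(DIRECTIONS, stimulus["direction"].to_numpy()[grating])
    c_idx = np.searchsorted(CONTRASTS, stimulus["contrast"].to_numpy()[grating])
    codes[grating] = d_idx * len(CONTRASTS) + c_idx
    return codes


def _chisq_from_sums(cond_sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Chi-square statistic from per-condition response sums.

    The statistic compares each condition's mean response O_i with the grand
    per-presentation mean E: sum_i (E - O_i)^2 / E.  Rows with E == 0 (an
    all-zero cell) return 0 by convention.
    """
    total = cond_sums.sum(axis=-1)
    n = counts.sum()
    expected = total / n
    observed = cond_sums / counts
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = ((expected[..., None] - observed) ** 2).sum(axis=-1) / expected
    return np.where(expected > 0, chi2, 0.0)


def chisq_responsiveness(
    responses: np.ndarray,
    stimulus: pd.DataFrame,
    n_shuffles: int = 200_000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
    method: str = "bootstrap",
) -> tuple[float, float]:
    """Bootstrapped chi-square test for stimulus responsiveness of one cell.

    The observed statistic is compared against a null distribution built by
    resampling the cell's responses across all presentations -- with
    replacement (``method="bootstrap"``, the default) or without
    (``method="permutation"``).  The p-value uses +1 smoothing:
    ``p = (1 + #null >= observed) / (1 + n_shuffles)``; the cell is called
    responsive when ``p < alpha``.
    """
    chi2, p = chisq_responsiveness_batch(
        np.asarray(responses, dtype=float)[None, :],
        stimulus,
        n_shuffles=n_shuffles,
        seed=seed,
        method=method,
    )
    return float(chi2[0]), float(p[0])


def chisq_responsiveness_batch(
    responses: np.ndarray,
    stimulus: pd.DataFrame,
    n_shuffles: int = 200_000,
    seed: int | np.random.Generator = 0,
    method: str = "bootstrap",
    chunk: int = 20_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`chisq_responsiveness` over a (cells x trials) matrix."""
    if method not in ("bootstrap", "permutation"):
        raise ValueError(f"method must be 'bootstrap' or 'permutation', got {method!r}")
    responses = np.asarray(responses, dtype=float)
    codes = condition_codes(stimulus)
    if np.unique(codes).size != N_CONDITIONS:
        raise ConfigurationError(
            f"all {N_CONDITIONS} conditions (48 gratings + blank) must be present"
        )
    rng = np.random.default_rng(seed)
    order = np.argsort(codes, kind="stable")
    boundaries = np.flatnonzero(np.diff(codes[order], prepend=-1))
    counts = np.diff(np.append(boundaries, codes.size))
    n_trials = codes.size

    chi2_obs = np.empty(responses.shape[0])
    p = np.empty(responses.shape[0])
    for ci, cell in enumerate(responses):
        ordered = cell[order]
        sums = np.add.reduceat(ordered, boundaries)
        obs = _chisq_from_sums(sums, counts)
        exceed = 0
        done = 0
        while done < n_shuffles:
            m = min(chunk, n_shuffles - done)
            if method == "bootstrap":
                draws = cell[rng.integers(0, n_trials, size=(m, n_trials))]
            else:
                draws = rng.permuted(np.broadcast_to(ordered, (m, n_trials)), axis=1)
            null_sums = np.add.reduceat(draws, boundaries, axis=1)
            null = _chisq_from_sums(null_sums, counts)
            exceed += int((null >= obs).sum())
            done += m
        chi2_obs[ci] = obs
        p[ci] = (1.0 + exceed) / (1.0 + n_shuffles)
    return chi2_obs, p


@dataclass
class ConditionResponseTable:
    """Blank-subtracted condition responses and their bootstrap percentiles.

    ``table`` has one row per grating condition (direction, contrast) with
    the presentation count ``m``, observed mean ``observed``, the
    blank-subtracted mean ``rbar`` and its percentile within the cell's own
    bootstrap null.  ``pooled`` holds the same quantities for all-direction
    pools at each contrast (used by the family-wise suppression variant).
    """

    table: pd.DataFrame
    pooled: pd.DataFrame
    blank_mean: float
    grand_mean: float
    n_boot: int


def condition_response_stats(
    responses: np.ndarray,
    stimulus: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> ConditionResponseTable:
    """Per-condition blank-subtracted means and bootstrap-null percentiles.

    The null for a condition with ``m`` presentations is the distribution of
    (mean of ``m`` draws) - (mean of ``m_blank`` draws), both resampled with
    replacement from all of the cell's responses.  Percentiles use midranks
    for ties so a constant cell sits at 0.5.
    """
    responses = np.asarray(responses, dtype=float)
    codes = condition_codes(stimulus)
    blank_code = len(DIRECTIONS) * len(CONTRASTS)
    blank_mask = codes == blank_code
    m_blank = int(blank_mask.sum())
    if m_blank == 0:
        raise ConfigurationError("no blank trials in stimulus table")
    rng = np.random.default_rng(seed)
    blank_mean = float(responses[blank_mask].mean())
    grand_mean = float(responses.mean())
    n_trials = responses.size

    rows = []
    for d_idx, direction in enumerate(DIRECTIONS):
        for c_idx, contrast in enumerate(CONTRASTS):
            mask = codes == d_idx * len(CONTRASTS) + c_idx
            rows.append(
                {
                    "direction": direction,
                    "contrast": contrast,
                    "m": int(mask.sum()),
                    "observed": float(responses[mask].mean()),
                }
            )
    table = pd.DataFrame(rows)
    table["rbar"] = table["observed"] - blank_mean

    pooled_rows = []
    for c_idx, contrast in enumerate(CONTRASTS):
        mask = (codes % len(CONTRASTS) == c_idx) & ~blank_mask
        pooled_rows.append(
            {
                "contrast": contrast,
                "m": int(mask.sum()),
                "observed": float(responses[mask].mean()),
            }
        )
    pooled = pd.DataFrame(pooled_rows)
    pooled["rbar"] = pooled["observed"] - blank_mean

    # The null depends only on the sample sizes, so build one null
    # distribution per distinct m and share it across conditions.
    null_blank = responses[rng.integers(0, n_trials, size=(n_boot, m_blank))].mean(axis=1)
    nulls: dict[int, np.ndarray] = {}
    for m in set(table["m"]).union(pooled["m"]):
        cond = responses[rng.integers(0, n_trials, size=(n_boot, m))].mean(axis=1)
        nulls[m] = cond - null_blank

    def _percentile(rbar: float, m: int) -> float:
        null = nulls[m]
        return float(((null < rbar).sum() + 0.5 * (null == rbar).sum()) / n_boot)

    table["percentile"] = [
        _percentile(r, m) for r, m in zip(table["rbar"], table["m"])
    ]
    pooled["percentile"] = [
        _percentile(r, m) for r, m in zip(pooled["rbar"], pooled["m"])
    ]
    return ConditionResponseTable(table, pooled, blank_mean, grand_mean, n_boot)


def suppressed_by_contrast(
    crt: ConditionResponseTable,
    variant: str = "peak_direction",
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> bool:
    """Suppression-by-contrast under either published definition.

    ``"peak_direction"``: the percentile of the blank-subtracted response at
    the cell's peak direction and 80% contrast is below ``alpha``.
    ``"all_directions"``: the percentile of the pooled response over all
    directions at 80% contrast is below ``alpha`` family-wise corrected
    across the six contrasts (Bonferroni or Sidak).
    """
    high = CONTRASTS[-1]
    if variant == "peak_direction":
        peak_row = crt.table.loc[crt.table["observed"].idxmax()]
        row = crt.table[
            (crt.table["direction"] == peak_row["direction"])
            & (crt.table["contrast"] == high)
        ].iloc[0]
        return bool(row["percentile"] < alpha)
    if variant == "all_directions":
        n_comp = len(CONTRASTS)
        if correction == "bonferroni":
            threshold = alpha / n_comp
        elif correction == "sidak":
            threshold = 1.0 - (1.0 - alpha) ** (1.0 / n_comp)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        row = crt.pooled[crt.pooled["contrast"] == high].iloc[0]
        return bool(row["percentile"] < threshold)
    raise ValueError(f"unknown variant {variant!r}")


def gosi(
    responses_by_direction: np.ndarray,
    directions: np.ndarray = DIRECTIONS,
    convention: str = "doubled_angle",
) -> float:
    """Global orientation selectivity index: |sum R e^(i theta')| / sum R.

    The default convention doubles the angles (so opposite directions count
    as the same orientation); ``convention="literal"`` uses the raw
    direction angles.
    """
    r = np.asarray(responses_by_direction, dtype=float)
    if np.any(r < 0):
        raise ValueError("responses must be nonnegative")
    total = r.sum()
    if total == 0:
        return float("nan")
    if convention == "doubled_angle":
        angles = 2.0 * np.radians(directions)
    elif convention == "literal":
        angles = np.radians(directions)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(np.abs((r * np.exp(1j * angles)).sum()) / total)


def dsi(r_pref: float, r_null: float) -> float:
    """Direction selectivity index (R_pref - R_null) / (R_pref + R_null)."""
    if r_pref + r_null == 0:
        return float("nan")
    return float((r_pref - r_null) / (r_pref + r_null))


def dsi_from_tuning(
    responses_by_direction: np.ndarray, directions: np.ndarray = DIRECTIONS
) -> float:
    """DSI from an 8-point direction tuning curve (null = opposite of peak)."""
    r = np.asarray(responses_by_direction, dtype=float)
    pref_idx = int(np.argmax(r))
    null_dir = (directions[pref_idx] + 180.0) % 360.0
    null_idx = int(np.argmin(np.abs(directions - null_dir)))
    return dsi(float(r[pref_idx]), float(r[null_idx]))


def contrast_com(
    responses_by_contrast: np.ndarray, contrasts: np.ndarray = CONTRASTS
) -> float:
    """cCoM = exp(sum R ln c / sum R): log-scaled contrast center of mass."""
    r = np.asarray(responses_by_contrast, dtype=float)
    if np.any(r < 0):
        raise ValueError("responses must be nonnegative")
    total = r.sum()
    if total == 0:
        return float("nan")
    return float(np.exp((r * np.log(contrasts)).sum() / total))


@dataclass
class PopulationBias:
    """Vector-sum direction bias of a population of preferred directions."""

    theta_bias: float  # degrees
    r_bias: float  # normalized resultant, in [0, 1]
    null_ci_radius: float  # corrected 95% radius under a uniform population
    n_cells: int


def population_direction_bias(
    preferred_directions: np.ndarray,
    n_null: int = 10_000,
    n_contrast_comparisons: int = 6,
    alpha: float = 0.05,
    correction: str = "sidak",
    seed: int | np.random.Generator = 0,
) -> PopulationBias:
    """Direction and magnitude of the vector sum of direction preferences.

    The null confidence radius is the corrected (1 - alpha) quantile of
    ``r_bias`` for populations of the same size with direction preferences
    drawn uniformly from the eight stimulus directions; the correction
    accounts for testing at each of the six contrasts.
    """
    theta = np.radians(np.asarray(preferred_directions, dtype=float))
    if theta.size == 0:
        raise ValueError("population is empty")
    rng = np.random.default_rng(seed)
    s, c = np.sin(theta).sum(), np.cos(theta).sum()
    theta_bias = float(np.degrees(np.arctan2(s, c))) % 360.0
    r_bias = float(np.hypot(c, s) / theta.size)

    if correction == "sidak":
        alpha_corr = 1.0 - (1.0 - alpha) ** (1.0 / n_contrast_comparisons)
    elif correction == "bonferroni":
        alpha_corr = alpha / n_contrast_comparisons
    else:
        raise ValueError(f"unknown correction {correction!r}")
    null_theta = np.radians(rng.choice(DIRECTIONS, size=(n_null, theta.size)))
    null_r = (
        np.hypot(np.cos(null_theta).sum(axis=1), np.sin(null_theta).sum(axis=1))
        / theta.size
    )
    radius = float(np.quantile(null_r, 1.0 - alpha_corr))
    return PopulationBias(theta_bias, r_bias, radius, int(theta.size))


def normalized_response(r_dc, r_b, r_bar_dc):
    """RN = (R_dc - R_b) / (R_bar_dc + R_b); NaN where the denominator is 0."""
    r_dc = np.asarray(r_dc, dtype=float)
    denom = np.asarray(r_bar_dc, dtype=float) + r_b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (r_dc - r_b) / denom
    out = np.where(denom != 0, out, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class LocomotionSplit:
    """Run/stationary trial split with per-condition inclusion flags."""

    run_state: np.ndarray  # bool per trial
    table: pd.DataFrame  # per condition: n_run, n_stationary, included
    speed_threshold: float
    min_trials: int = 4

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]


def split_by_locomotion(
    stimulus: pd.DataFrame,
    speed_threshold: float = RUN_SPEED_THRESHOLD,
    min_trials: int = 4,
) -> LocomotionSplit:
    """Classify trials as running (speed >= threshold) vs stationary.

    A (direction, contrast) condition is included in locomotion-conditioned
    averages only when it has at least ``min_trials`` running *and*
    ``min_trials`` stationary presentations.
    """
    run_state = stimulus["run_speed"].to_numpy() >= speed_threshold
    codes = condition_codes(stimulus)
    rows = []
    labels = [(d, c) for d in DIRECTIONS for c in CONTRASTS] + [(np.nan, 0.0)]
    for code, (d, c) in enumerate(labels):
        mask = codes == code
        n_run = int((mask & run_state).sum())
        n_stat = int((mask & ~run_state).sum())
        rows.append(
            {
                "direction": d,
                "contrast": c,
                "is_blank": code == len(labels) - 1,
                "n_run": n_run,
                "n_stationary": n_stat,
                "included": n_run >= min_trials and n_stat >= min_trials,
            }
        )
    return LocomotionSplit(run_state, pd.DataFrame(rows), speed_threshold, min_trials)


def population_tuning_summary(
    responses: np.ndarray,
    stimulus: pd.DataFrame,
    split: LocomotionSplit | None = None,
    responsive: np.ndarray | None = None,
    min_responsive: int = 3,
) -> dict[str, pd.DataFrame]:
    """Blank-subtracted population mean +/- SEM per (direction, contrast, state).

    Returns a dict with ``"surface"`` (the full mean/SEM surface), and the
    derived ``"contrast_curves"`` (at the population peak direction) and
    ``"direction_curves"`` (averaged over low 5-10% and high 60-80%
    contrasts).  Cells enter only if ``responsive``; an experiment needs at
    least ``min_responsive`` responsive cells, otherwise the summary is
    empty (with a warning).
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if split is None:
        split = split_by_locomotion(stimulus)
    if responsive is None:
        responsive = np.ones(responses.shape[0], dtype=bool)
    responses = responses[np.asarray(responsive, dtype=bool)]
    empty = {
        "surface": pd.DataFrame(
            columns=["direction", "contrast", "state", "mean", "sem", "n_cells"]
        ),
        "contrast_curves": pd.DataFrame(),
        "direction_curves": pd.DataFrame(),
    }
    if responses.shape[0] < min_responsive:
        logger.warning(
            "only %d responsive cells (< %d); returning empty summary",
            responses.shape[0],
            min_responsive,
        )
        return empty

    codes = condition_codes(stimulus)
    blank_code = len(DIRECTIONS) * len(CONTRASTS)
    rows = []
    for state, state_name in ((True, "run"), (False, "stationary")):
        state_mask = split.run_state == state
        blank_sel = (codes == blank_code) & state_mask
        if not blank_sel.any():
            continue
        blank_means = responses[:, blank_sel].mean(axis=1)
        for d_idx, d in enumerate(DIRECTIONS):
            for c_idx, c in enumerate(CONTRASTS):
                code = d_idx * len(CONTRASTS) + c_idx
                inc = split.table[
                    (split.table["direction"] == d) & (split.table["contrast"] == c)
                ]["included"].iloc[0]
                sel = (codes == code) & state_mask
                if not inc or not sel.any():
                    mean = sem = np.nan
                else:
                    per_cell = responses[:, sel].mean(axis=1) - blank_means
                    mean = float(per_cell.mean())
                    sem = float(per_cell.std(ddof=1) / np.sqrt(per_cell.size))
                rows.append(
                    {
                        "direction": d,
                        "contrast": c,
                        "state": state_name,
                        "mean": mean,
                        "sem": sem,
                        "n_cells": responses.shape[0],
                    }
                )
    surface = pd.DataFrame(rows)
    if surface.empty:
        return empty

    by_dir = surface.groupby("direction")["mean"].mean()
    peak_direction = float(by_dir.idxmax())
    contrast_curves = surface[surface["direction"] == peak_direction].copy()
    contrast_curves["peak_direction"] = peak_direction

    low = surface[surface["contrast"].isin(CONTRASTS[:2])]
    high = surface[surface["contrast"].isin(CONTRASTS[-2:])]
    dir_rows = []
    for band_name, band in (("low", low), ("high", high)):
        agg = band.groupby(["direction", "state"], as_index=False)["mean"].mean()
        agg["band"] = band_name
        dir_rows.append(agg)
    direction_curves = pd.concat(dir_rows, ignore_index=True)
    return {
        "surface": surface,
        "contrast_curves": contrast_curves,
        "direction_curves": direction_curves,
    }


def compute_cell_metrics(
    responses: np.ndarray,
    stimulus: pd.DataFrame,
    n_shuffles: int = 2000,
    n_boot: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-cell metric table for a (cells x trials) response matrix."""
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    rng = np.random.default_rng(seed)
    chi2, p = chisq_responsiveness_batch(
        responses, stimulus, n_shuffles=n_shuffles, seed=rng
    )
    codes = condition_codes(stimulus)
    rows = []
    for i, cell in enumerate(responses):
        cond_means = np.array(
            [
                cell[codes == d * len(CONTRASTS) + c].mean()
                for d in range(len(DIRECTIONS))
                for c in range(len(CONTRASTS))
            ]
        ).reshape(len(DIRECTIONS), len(CONTRASTS))
        flat_idx = int(np.argmax(cond_means))  # ties -> lowest index
        pref_d_idx, pref_c_idx = np.unravel_index(flat_idx, cond_means.shape)
        crt = condition_response_stats(cell, stimulus, n_boot=n_boot, seed=rng)
        rows.append(
            {
                "neuron_id": i,
                "chi2": chi2[i],
                "p_value": p[i],
                "responsive": p[i] < alpha,
                "preferred_direction": DIRECTIONS[pref_d_idx],
                "preferred_contrast": CONTRASTS[pref_c_idx],
                "gOSI": gosi(cond_means[:, pref_c_idx]),
                "DSI": dsi_from_tuning(cond_means[:, pref_c_idx]),
                "cCoM": contrast_com(cond_means[pref_d_idx, :]),
                "suppressed_peak": suppressed_by_contrast(crt, "peak_direction"),
                "suppressed_all": suppressed_by_contrast(crt, "all_directions"),
            }
        )
    return pd.DataFrame(rows)
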