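"""Contrast response function fitting and model comparison.

Trial responses at a cell's preferred direction are fit to three sigmoid
families with the slope fixed at ``s = 10`` (contrast as a fraction):

* high pass  (rising):  ``R(c) = b + h / (1 + exp(-s (c - c50r)))``
* low pass  (falling):  ``R(c) = b + h / (1 + exp( s (c - c50f)))``
* band pass (product):  ``R(c) = b + h * rising * falling``

Models are compared by AIC = 2k - 2 ln L.  Because event-magnitude
responses are far from normal, the default likelihood is estimated by
shuffling responses across trials and taking the fraction of shuffles whose
sum of squared residuals exceeds the observed one (with +1 smoothing so the
log never diverges); a closed-form normal likelihood is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synth import CONTRASTS

SLOPE = 10.0
KINDS = ("high_pass", "low_pass", "band_pass")
K_PARAMS = {"high_pass": 3, "low_pass": 3, "band_pass": 4}
C50_BOUNDS = (0.01, 1.0)
_C50_STARTS = (0.05, 0.1, 0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class SigmoidModel:
    """A fitted contrast sigmoid (slope fixed at :data:`SLOPE`)."""

    kind: str
    b: float
    h: float
    c50r: float | None = None
    c50f: float | None = None

    @property
    def k_params(self) -> int:
        return K_PARAMS[self.kind]

    def predict(self, contrast: np.ndarray) -> np.ndarray:
        c = np.asarray(contrast, dtype=float)
        out = np.full(c.shape, self.b, dtype=float)
        if self.kind in ("high_pass", "band_pass"):
            rise = 1.0 / (1.0 + np.exp(-SLOPE * (c - self.c50r)))
        if self.kind in ("low_pass", "band_pass"):
            fall = 1.0 / (1.0 + np.exp(SLOPE * (c - self.c50f)))
        if self.kind == "high_pass":
            return out + self.h * rise
        if self.kind == "low_pass":
            return out + self.h * fall
        return out + self.h * rise * fall


@dataclass
class FitResult:
    """One model's fit, bootstrap likelihood and AIC."""

    model: SigmoidModel
    ss: float
    log_likelihood: float | None = None
    aic: float | None = None
    n_shuffles: int | None = None
    converged: bool = True


def fit_sigmoid(contrasts: np.ndarray, responses: np.ndarray, kind: str) -> FitResult:
    """Least-squares fit of one sigmoid family to per-trial responses.

    Uses bounded optimization with a multi-start grid over the half-point
    parameter(s); the best (lowest-SS) start wins.  If no start converges
    the best iterate is still returned, flagged ``converged=False``.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    c = np.asarray(contrasts, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("need responses at >= 2 distinct contrasts")
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    # floor keeps the parameter box non-degenerate for flat/all-zero cells
    scale = max(y_hi - y_lo, y_hi, 1e-6)

    def residuals(params: np.ndarray) -> np.ndarray:
        model = _unpack(kind, params)
        return model.predict(c) - y

    best = None
    any_converged = False
    for start in _starts(kind, y_lo, y_hi, scale):
        lo, hi = _bounds(kind, scale)
        try:
            res = least_squares(residuals, start, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - optimizer failure is rare
            continue
        ss = float(2.0 * res.cost)
        any_converged = any_converged or bool(res.success)
        if best is None or ss < best[0]:
            best = (ss, res.x)
    if best is None:  # pragma: no cover
        raise RuntimeError("all optimization starts failed")
    ss, params = best
    return FitResult(_unpack(kind, params), ss, converged=any_converged)


def _unpack(kind: str, params: np.ndarray) -> SigmoidModel:
    if kind == "high_pass":
        return SigmoidModel(kind, params[0], params[1], c50r=params[2])
    if kind == "low_pass":
        return SigmoidModel(kind, params[0], params[1], c50f=params[2])
    return SigmoidModel(kind, params[0], params[1], c50r=params[2], c50f=params[3])


def _bounds(kind: str, scale: float) -> tuple[list, list]:
    lo = [0.0, 0.0, C50_BOUNDS[0]]
    hi = [10.0 * scale, 10.0 * scale, C50_BOUNDS[1]]
    if kind == "band_pass":
        lo.append(C50_BOUNDS[0])
        hi.append(C50_BOUNDS[1])
    return lo, hi


def _starts(kind: str, y_lo: float, y_hi: float, scale: float):
    b0 = max(y_lo, 1e-9)
    h0 = max(y_hi - y_lo, 1e-9)
    if kind == "band_pass":
        for c50r in _C50_STARTS:
            for c50f in _C50_STARTS:
                if c50r < c50f:
                    # Product peaks below h; start with a larger amplitude.
                    yield np.array([b0, 2.0 * h0, c50r, c50f])
    else:
        for c50 in _C50_STARTS:
            yield np.array([b0, h0, c50])


def bootstrap_loglik(
    responses: np.ndarray,
    predictions: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Shuffle-based log-likelihood of a model's per-trial predictions.

    The likelihood is the fraction of trial-shuffles whose SS against the
    predictions exceeds the observed SS, smoothed as
    ``(count + 1) / (n_shuffles + 1)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(responses, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    ss_obs = float(((y - yhat) ** 2).sum())
    shuffled = rng.permuted(np.broadcast_to(y, (n_shuffles, y.size)), axis=1)
    ss_null = ((shuffled - yhat) ** 2).sum(axis=1)
    likelihood = (float((ss_null > ss_obs).sum()) + 1.0) / (n_shuffles + 1.0)
    return float(np.log(likelihood))


def normal_loglik(responses: np.ndarray, predictions: np.ndarray) -> float:
    """Closed-form normal log-likelihood (up to a model-independent constant).

    Uses the variance of all of the cell's responses as the noise variance:
    ``ln L = -SS / (2 sigma_R^2)``.
    """
    y = np.asarray(responses, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    var = float(np.var(y))
    if var == 0:
        return 0.0
    return float(-((y - yhat) ** 2).sum() / (2.0 * var))


def aic(k_params: int, log_likelihood: float) -> float:
    """Akaike information criterion, AIC = 2k - 2 ln L."""
    return 2.0 * k_params - 2.0 * log_likelihood


@dataclass
class ModelSelection:
    """Winner of the three-way contrast-model comparison."""

    kind: str | None  # None marks an unclassifiable (degenerate) cell
    fits: dict[str, FitResult]


def select_contrast_model(
    contrasts: np.ndarray,
    responses: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    likelihood: str = "bootstrap",
) -> ModelSelection:
    """Fit all three sigmoid families and pick the lowest-AIC model.

    Ties break toward fewer parameters, then toward ``high_pass`` (fixed
    order), so selection is deterministic.  A cell with no variance at all
    cannot be ranked by the shuffle likelihood and is returned unclassified.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(responses, dtype=float)
    c = np.asarray(contrasts, dtype=float)
    fits: dict[str, FitResult] = {}
    for kind in KINDS:
        fit = fit_sigmoid(c, y, kind)
        pred = fit.model.predict(c)
        if likelihood == "bootstrap":
            logl = bootstrap_loglik(y, pred, n_shuffles=n_shuffles, seed=rng)
            fit.n_shuffles = n_shuffles
        elif likelihood == "normal":
            logl = normal_loglik(y, pred)
        else:
            raise ValueError(f"unknown likelihood {likelihood!r}")
        fit.log_likelihood = logl
        fit.aic = aic(fit.model.k_params, logl)
        fits[kind] = fit
    if np.all(y == 0):
        return ModelSelection(None, fits)
    order = {"high_pass": 0, "low_pass": 1, "band_pass": 2}
    winner = min(fits, key=lambda k: (fits[k].aic, fits[k].model.k_params, order[k]))
    return ModelSelection(winner, fits)


def classify_cells(
    contrasts_per_trial: np.ndarray,
    responses: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[ModelSelection]:
    """Run model selection for each row of a (cells x trials) matrix."""
    rng = np.random.default_rng(seed)
    return [
        select_contrast_model(contrasts_per_trial, cell, n_shuffles=n_shuffles, seed=rng)
        for cell in np.atleast_2d(responses)
    ]
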