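"""126-term L1-regularized exponential-link model of population responses.

The trial-wise population response (mean event magnitude across a cell
class) is predicted from binary trial attributes: blank, run state, 8
directions, 6 contrasts, and all run/direction/contrast interactions --
1 + 1 + 8 + 6 + 8 + 6 + 48 + 48 = 126 predictors plus an unpenalized
constant.  The predicted response is ``exp(w . a + k)`` and the fitted cost
is ``SSE + lambda * sum |w|`` (an optional Poisson deviance objective is
available), minimized by iteratively reweighted least squares whose
quadratic subproblem is solved by an accelerated proximal-gradient
(soft-threshold) step, with a step-halving line search so the objective
never increases across iterations.  ``lambda`` is chosen by
leave-one-session-out cross validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CONTRASTS, DIRECTIONS

N_TERMS = 126
_ETA_CLIP = 30.0


class GLMDivergenceError(RuntimeError):
    """Optimization diverged; carries the last iterate for inspection."""

    def __init__(self, message: str, fit: "GLMFit"):
        super().__init__(message)
        self.fit = fit


def term_names() -> list[str]:
    """Canonical column order of the 126 predictors."""
    names = ["blank", "run"]
    names += [f"dir:{int(d)}" for d in DIRECTIONS]
    names += [f"con:{c:g}" for c in CONTRASTS]
    names += [f"run:dir:{int(d)}" for d in DIRECTIONS]
    names += [f"run:con:{c:g}" for c in CONTRASTS]
    names += [f"dir:{int(d)}:con:{c:g}" for d in DIRECTIONS for c in CONTRASTS]
    names += [f"run:dir:{int(d)}:con:{c:g}" for d in DIRECTIONS for c in CONTRASTS]
    return names


def build_design_matrix(stimulus: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """One binary row per trial in the canonical 126-column order.

    Blank trials activate only the blank term (plus run when running);
    grating trials activate direction, contrast and the matching
    interactions.
    """
    n = len(stimulus)
    blank = stimulus["is_blank"].to_numpy()
    run = stimulus["run_state"].to_numpy().astype(float)
    direction = stimulus["direction"].to_numpy()
    contrast = stimulus["contrast"].to_numpy()

    grating = ~blank
    bad_dir = grating & ~np.isin(direction, DIRECTIONS)
    bad_con = grating & ~np.isin(np.round(contrast, 10), np.round(CONTRASTS, 10))
    if bad_dir.any() or bad_con.any():
        rows = np.flatnonzero(bad_dir | bad_con)[:5].tolist()
        raise ValueError(f"unknown direction/contrast levels at rows {rows}")

    d_onehot = np.zeros((n, len(DIRECTIONS)))
    c_onehot = np.zeros((n, len(CONTRASTS)))
    gi = np.flatnonzero(grating)
    d_idx = np.searchsorted(DIRECTIONS, direction[gi])
    c_idx = np.searchsorted(CONTRASTS, contrast[gi])
    d_onehot[gi, d_idx] = 1.0
    c_onehot[gi, c_idx] = 1.0
    dc = (d_onehot[:, :, None] * c_onehot[:, None, :]).reshape(n, -1)

    X = np.hstack(
        [
            blank.astype(float)[:, None],
            run[:, None],
            d_onehot,
            c_onehot,
            run[:, None] * d_onehot,
            run[:, None] * c_onehot,
            dc,
            run[:, None] * dc,
        ]
    )
    assert X.shape[1] == N_TERMS
    return X, term_names()


@dataclass
class GLMFit:
    """Fitted weights, penalty and diagnostics of one L1 GLM solve."""

    w: np.ndarray  # (126,) penalized weights
    k: float  # unpenalized constant (log-rate scale)
    lam: float
    sse: float
    l1: float
    objective: str = "sse"
    n_iter: int = 0
    converged: bool = True
    names: list[str] = field(default_factory=term_names)

    @property
    def cost(self) -> float:
        return self.sse + self.lam * self.l1

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(X @ self.w + self.k, -_ETA_CLIP, _ETA_CLIP)
        return np.exp(eta)


def _objective(X, y, counts, w, k, lam, objective):
    eta = np.clip(X @ w + k, -_ETA_CLIP, _ETA_CLIP)
    yhat = np.exp(eta)
    if objective == "sse":
        data_term = float((counts * (y - yhat) ** 2).sum())
    else:  # poisson deviance (up to a data-only constant)
        data_term = float(2.0 * (counts * (yhat - y * eta)).sum())
    return data_term + lam * float(np.abs(w).sum()), yhat, eta


def _compress(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group trials by identical design rows.

    Both the SSE and the Poisson-deviance data terms decompose over groups
    of identical covariate patterns into a weighted term in the group means
    plus a parameter-independent constant, so fitting on the (at most 98)
    unique rows with group counts is exact and much faster.
    """
    uniq, inverse, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros(len(uniq))
    np.add.at(sums, inverse, y)
    return uniq, sums / counts, counts.astype(float)


def _weighted_lasso(
    X: np.ndarray,
    z: np.ndarray,
    weights: np.ndarray,
    lam: float,
    w0: np.ndarray,
    k0: float,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """FISTA on ``sum_i weights_i (z_i - X w - k)^2 + lam * |w|``.

    The constant ``k`` rides along as an unpenalized extra coordinate.
    Returns the (approximate) minimizer starting from ``(w0, k0)``.
    """
    sw = np.sqrt(weights)
    A = np.hstack([X, np.ones((X.shape[0], 1))]) * sw[:, None]
    b = z * sw
    # Lipschitz constant of the smooth part: 2 * sigma_max(A)^2 (power iter).
    v = np.ones(A.shape[1]) / np.sqrt(A.shape[1])
    for _ in range(30):
        v = A.T @ (A @ v)
        norm = np.linalg.norm(v)
        if norm == 0:
            return w0.copy(), k0
        v /= norm
    L = 2.0 * norm
    step = 1.0 / L

    x = np.append(w0, k0)
    yv = x.copy()
    t_acc = 1.0
    for _ in range(max_iter):
        grad = 2.0 * (A.T @ (A @ yv - b))
        x_new = yv - step * grad
        x_new[:-1] = np.sign(x_new[:-1]) * np.maximum(
            np.abs(x_new[:-1]) - step * lam, 0.0
        )
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        yv = x_new + (t_acc - 1.0) / t_new * (x_new - x)
        delta = float(np.max(np.abs(x_new - x)))
        x, t_acc = x_new, t_new
        if delta < tol:
            break
    return x[:-1], float(x[-1])


def fit_l1(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    objective: str = "sse",
    tol: float = 1e-8,
    max_iter: int = 500,
    n_inner: int = 1000,
) -> GLMFit:
    """Minimize ``SSE + lambda * l1`` (or Poisson deviance + l1) by IRLS.

    Each outer iteration forms the local weighted-least-squares model of the
    data term around the current linear predictor, solves it with an
    accelerated proximal-gradient (soft-threshold) step on the penalized
    weights (the constant is unpenalized), and applies a step-halving line
    search on the true objective.  Convergence is declared when the largest
    applied weight
    change falls below ``tol``.  Internally trials with identical design
    rows are pooled (exact for both objectives), so the solve cost does not
    grow with the number of trials.
    """
    if objective not in ("sse", "poisson"):
        raise ValueError(f"objective must be 'sse' or 'poisson', got {objective!r}")
    X_full = np.asarray(X, dtype=float)
    y_full = np.asarray(y, dtype=float)
    if np.any(y_full < 0):
        raise ValueError("responses must be nonnegative")
    X, y, counts = _compress(X_full, y_full)
    p = X.shape[1]
    w = np.zeros(p)
    k = float(np.log(max(y_full.mean(), 1e-12)))
    obj, yhat, eta = _objective(X, y, counts, w, k, lam, objective)

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # Gauss-Newton model of the data term: sum_i weights_i (z_i - eta'_i)^2
        # reproduces its gradient and (approximate) curvature at eta, so the
        # soft-threshold below applies the L1 penalty on the correct scale.
        weights = counts * (yhat**2 if objective == "sse" else yhat)
        z = eta + (y - yhat) / np.maximum(yhat, 1e-300)

        # Accelerated proximal-gradient (FISTA) solve of the subproblem
        #   min_v sum_i weights_i (z_i - A v)^2 + lam |v[:-1]|
        # with A = [X, 1] and the constant (last coordinate) unpenalized.
        w_new, k_new = _weighted_lasso(
            X, z, weights, lam, w, k, max_iter=n_inner, tol=0.01 * tol
        )

        step_w, step_k = w_new - w, k_new - k
        t = 1.0
        while t > 1e-12:
            obj_try, yhat_try, eta_try = _objective(
                X, y, counts, w + t * step_w, k + t * step_k, lam, objective
            )
            if np.isfinite(obj_try) and obj_try <= obj + 1e-12:
                break
            t *= 0.5
        else:
            break  # no descent possible: treat as converged at current point
        w = w + t * step_w
        k = k + t * step_k
        obj, yhat, eta = obj_try, yhat_try, eta_try
        applied = t * max(float(np.max(np.abs(step_w))), abs(step_k))
        if applied < tol:
            converged = True
            break

    eta_full = np.clip(X_full @ w + k, -_ETA_CLIP, _ETA_CLIP)
    sse = float(((y_full - np.exp(eta_full)) ** 2).sum())
    fit = GLMFit(
        w=w,
        k=float(k),
        lam=float(lam),
        sse=sse,
        l1=float(np.abs(w).sum()),
        objective=objective,
        n_iter=n_iter,
        converged=converged or n_iter == 0,
    )
    if not np.isfinite(obj):
        raise GLMDivergenceError("objective became non-finite", fit)
    return fit


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 16) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all-zero solution) downward."""
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    grad0 = X.T @ (2.0 * (y - ybar) * ybar)
    lam_max = float(np.max(np.abs(grad0)))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)


def cross_validate_lambda(
    X: np.ndarray,
    y: np.ndarray,
    session_ids: np.ndarray,
    lambdas: np.ndarray | None = None,
    objective: str = "sse",
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty by leave-one-session-out cross validation.

    Returns ``(lambda_star, cv_table)`` where ``cv_table`` has one row per
    (lambda, held-out session) with the held-out SSE.  ``lambda_star``
    minimizes the mean held-out SSE; ties break toward the larger (sparser)
    penalty.
    """
    session_ids = np.asarray(session_ids)
    sessions = np.unique(session_ids)
    if sessions.size < 2:
        raise ValueError("cross-validation needs >= 2 sessions")
    if lambdas is None:
        lambdas = lambda_grid(X, y)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    rows = []
    for lam in lambdas:
        for s in sessions:
            held = session_ids == s
            fit = fit_l1(X[~held], y[~held], lam, objective=objective)
            err = float(((y[held] - fit.predict(X[held])) ** 2).sum())
            rows.append({"lam": lam, "session": s, "sse": err})
    cv = pd.DataFrame(rows)
    mean_err = cv.groupby("lam")["sse"].mean()
    best = mean_err[mean_err == mean_err.min()]
    lam_star = float(best.index.max())  # ties -> sparser
    return lam_star, cv


def predict_response(fit: GLMFit, X: np.ndarray) -> np.ndarray:
    """Predicted response ``exp(w . a + k)`` for design rows ``X``."""
    return fit.predict(np.atleast_2d(np.asarray(X, dtype=float)))


def prediction_surface(fit: GLMFit) -> pd.DataFrame:
    """Stimulus-minus-blank predicted responses per run state.

    Builds one design row per (run state, direction, contrast) plus the two
    blank rows, and returns long-format predictions with the same-state
    blank prediction subtracted.
    """
    rows = []
    for run in (0, 1):
        stim = pd.DataFrame(
            {
                "is_blank": [True],
                "run_state": [bool(run)],
                "direction": [np.nan],
                "contrast": [0.0],
            }
        )
        Xb, _ = build_design_matrix(stim)
        blank_pred = float(fit.predict(Xb)[0])
        for d in DIRECTIONS:
            for c in CONTRASTS:
                stim = pd.DataFrame(
                    {
                        "is_blank": [False],
                        "run_state": [bool(run)],
                        "direction": [d],
                        "contrast": [c],
                    }
                )
                Xs, _ = build_design_matrix(stim)
                rows.append(
                    {
                        "run": bool(run),
                        "direction": d,
                        "contrast": c,
                        "prediction_minus_blank": float(fit.predict(Xs)[0]) - blank_pred,
                    }
                )
    return pd.DataFrame(rows)


def weight_table(fit: GLMFit) -> pd.DataFrame:
    """Long-format weights keyed by term type (heatmap-ready)."""
    rows = []
    for name, w in zip(fit.names, fit.w):
        parts = name.split(":")
        run = parts[0] == "run" or name == "run"
        direction = contrast = np.nan
        if "dir" in parts:
            direction = float(parts[parts.index("dir") + 1])
        if "con" in parts:
            contrast = float(parts[parts.index("con") + 1])
        if name == "blank":
            term_type = "blank"
        elif name == "run":
            term_type = "run"
        else:
            kind = []
            if run:
                kind.append("run")
            if not np.isnan(direction):
                kind.append("direction")
            if not np.isnan(contrast):
                kind.append("contrast")
            term_type = "x".join(kind)
        rows.append(
            {
                "term": name,
                "term_type": term_type,
                "run": run,
                "direction": direction,
                "contrast": contrast,
                "weight": w,
            }
        )
    return pd.DataFrame(rows)
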