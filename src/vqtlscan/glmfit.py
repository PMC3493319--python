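"""Light-weight weighted least squares and IRLS fitters.

These are deliberately minimal dense-matrix routines: every design in
this package has a handful of columns, and the dispersion-test benchmark
fits tens of thousands of such models, so the per-fit overhead matters
more than generality. All solvers work on the normal equations via
Cholesky-backed ``scipy.linalg.solve`` and raise on rank deficiency.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .errors import DegenerateFitError, DivergenceError

__all__ = ["wls", "leverages_from_factor", "gamma_glm_log", "poisson_glm_log"]

# linear predictors beyond this overflow exp() in double precision
ETA_LIMIT = 700.0


def wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Weighted least squares.

    Returns ``(beta, XtWX_inv)`` where ``XtWX_inv`` is the inverse of the
    weighted normal matrix (the unscaled coefficient covariance).
    """
    Xw = X if w is None else X * w[:, None]
    XtWX = X.T @ Xw
    Xty = Xw.T @ y
    try:
        c, low = linalg.cho_factor(XtWX, check_finite=False)
    except linalg.LinAlgError as exc:
        raise DegenerateFitError(f"rank-deficient or singular design: {exc}") from None
    beta = linalg.cho_solve((c, low), Xty, check_finite=False)
    XtWX_inv = linalg.cho_solve((c, low), np.eye(X.shape[1]), check_finite=False)
    return beta, XtWX_inv


def leverages_from_factor(X: np.ndarray, XtWX_inv: np.ndarray, w: np.ndarray | None):
    """Diagonal of the (weighted) hat matrix given (X'WX)^{-1}.

    h_ii = w_i x_i' (X'WX)^{-1} x_i, i.e. diag(W^1/2 X (X'WX)^{-1} X' W^1/2).
    """
    h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X)
    if w is not None:
        h = h * w
    return h


def gamma_glm_log(
    d: np.ndarray,
    X: np.ndarray,
    prior_weights: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Gamma GLM with log link, fitted by IRLS.

    With the log link and gamma variance function the IRLS working
    weights reduce to the prior weights, so each step is a WLS solve of
    the working response ``eta + d/mu - 1`` with a fixed weight vector.

    Returns ``(coef, cov_unit, converged)`` where ``cov_unit`` is
    ``(X'WX)^{-1}``, the coefficient covariance for unit gamma dispersion.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DegenerateFitError("gamma response must be strictly positive")
    if start is not None and np.all(np.isfinite(start)):
        coef = np.asarray(start, dtype=float).copy()
        eta = X @ coef
    else:
        mu0 = np.maximum(d, d.mean() * 1e-3)
        eta = np.log(mu0)
        coef = None
    if prior_weights is None:
        prior_weights = np.ones(len(d))
    converged = False
    cov = None
    for _ in range(max_iter):
        if np.max(np.abs(eta)) > ETA_LIMIT:
            raise DivergenceError("gamma GLM linear predictor overflow")
        mu = np.exp(eta)
        z = eta + d / mu - 1.0
        new_coef, cov = wls(X, z, prior_weights)
        eta = X @ new_coef
        if coef is not None and np.max(
            np.abs(new_coef - coef) / (1.0 + np.abs(coef))
        ) < tol:
            coef = new_coef
            converged = True
            break
        coef = new_coef
    return coef, cov, converged


def poisson_glm_log(
    y: np.ndarray,
    X: np.ndarray,
    prior_weights: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Poisson GLM with log link (IRLS), supporting prior weights.

    Returns ``(coef, cov, mu, working_weights, converged)``; ``cov`` is
    ``(X'WX)^{-1}`` with W the final IRLS weights ``prior_weights * mu``.
    """
    y = np.asarray(y, dtype=float)
    if prior_weights is None:
        prior_weights = np.ones(len(y))
    if start is not None and np.all(np.isfinite(start)):
        coef = np.asarray(start, dtype=float).copy()
        eta = X @ coef
    else:
        mu0 = y + y.mean() if y.mean() > 0 else y + 0.5
        eta = np.log(np.maximum(mu0, 1e-8))
        coef = None
    converged = False
    cov = None
    w = None
    mu = None
    for _ in range(max_iter):
        if np.max(np.abs(eta)) > ETA_LIMIT:
            raise DivergenceError("Poisson GLM linear predictor overflow")
        mu = np.exp(eta)
        w = prior_weights * mu
        z = eta + (y - mu) / mu
        new_coef, cov = wls(X, z, w)
        eta = X @ new_coef
        if coef is not None and np.max(
            np.abs(new_coef - coef) / (1.0 + np.abs(coef))
        ) < tol:
            coef = new_coef
            converged = True
            break
        coef = new_coef
    mu = np.exp(eta)
    w = prior_weights * mu
    return coef, cov, mu, w, converged
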