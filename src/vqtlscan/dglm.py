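"""Double generalized linear models (DGLM) and the dispersion test.

A DGLM jointly fits a mean submodel and a log-linear dispersion
submodel. For a Gaussian trait the model is

    y_i ~ N(x_i' beta, sigma_i^2),   log(sigma_i^2) = z_i' lambda,

estimated by cycling between (i) weighted least squares of y with
weights 1/sigma_i^2 and (ii) a gamma GLM with log link fitted to the
leverage-corrected squared residuals e_i^2 / (1 - h_ii) with prior
weights (1 - h_ii)/2, until the coefficients stabilise. The leverage
correction removes the downward bias of estimated squared residuals:
E(e_i^2) = (1 - h_ii) sigma_i^2 under the mean model.

For a Poisson-distributed count trait the mean submodel is a log-link
Poisson fit with prior weights 1/phi_i and the dispersion response is the
unit deviance d_i = 2[y_i log(y_i/mu_i) - (y_i - mu_i)], leverage-
corrected and modelled on the log scale exactly as above; inference uses
the extended quasi-likelihood (EQL).

A genotype term in the dispersion design makes the fitted model a vQTL
test: the likelihood-ratio statistic compares the full dispersion design
[1, g] against the intercept-only null (the mean submodel keeps g in
both), referred to chi^2(1). A Wald alternative uses the gamma-submodel
coefficient and its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .data import VQTLTestResult
from .errors import DivergenceError, MonomorphicError, ValidationError
from .glmfit import ETA_LIMIT, gamma_glm_log, leverages_from_factor, poisson_glm_log, wls

__all__ = ["DGLMSpec", "DGLMFit", "dglm_fit", "dglm_vqtl_test", "leverages"]


@dataclass
class DGLMSpec:
    """Design of a double GLM fit.

    family : 'gaussian' or 'poisson'
        Sampling distribution of the trait (Poisson requires non-negative
        integer responses).
    mean_design : (n, p_m) array
        Design of the mean submodel (intercept, covariates, dosage).
    disp_design : (n, p_d) array
        Design of the log-dispersion submodel.
    max_iter, tol
        Outer-loop control: stop when the largest scaled coefficient
        change max |delta| / (1 + |coef|) over (beta, lambda) drops
        below ``tol``.
    """

    family: str
    mean_design: np.ndarray
    disp_design: np.ndarray
    max_iter: int = 100
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown family {self.family!r}")
        self.mean_design = np.asarray(self.mean_design, dtype=float)
        self.disp_design = np.asarray(self.disp_design, dtype=float)
        n = self.mean_design.shape[0]
        if self.disp_design.shape[0] != n:
            raise ValidationError("mean and dispersion designs disagree on n")
        for name, X in (("mean", self.mean_design), ("dispersion", self.disp_design)):
            if n <= X.shape[1]:
                raise ValidationError(f"{name} design has n <= p")
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValidationError(f"{name} design is rank deficient")


@dataclass
class DGLMFit:
    """Converged (or best-effort) state of a double GLM."""

    beta: np.ndarray          # mean-submodel coefficients
    lam: np.ndarray           # log-dispersion coefficients
    sigma2: np.ndarray        # per-observation variance (gaussian) / dispersion phi (poisson)
    leverages: np.ndarray     # hat values of the weighted mean fit
    loglik: float             # exact gaussian log-likelihood, or EQL (poisson)
    n_iter: int
    converged: bool
    beta_cov: np.ndarray      # covariance of beta at convergence
    lam_cov: np.ndarray       # covariance of lambda from the gamma submodel
    fitted_mean: np.ndarray
    family: str
    warnings: list[str] = field(default_factory=list)


def leverages(X: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Hat values h_ii = diag(W^1/2 X (X'WX)^{-1} X' W^1/2).

    Their sum equals the number of columns of X (trace of a projection),
    and each lies in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    if w is not None:
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("weights must be strictly positive")
    _, XtWX_inv = wls(X, np.zeros(X.shape[0]), w)
    return leverages_from_factor(X, XtWX_inv, w)


def _gaussian_loglik(e: np.ndarray, sigma2: np.ndarray) -> float:
    return float(-0.5 * np.sum(np.log(2.0 * np.pi * sigma2) + e * e / sigma2))


def _poisson_unit_deviance(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    # y*log(y/mu) with the 0*log(0) = 0 convention
    return 2.0 * (special.xlogy(y, y / mu) - (y - mu))


def _poisson_eql(dev: np.ndarray, phi: np.ndarray) -> float:
    # extended quasi-likelihood up to an additive data-only constant
    # (the -1/2 log(2 pi V(y)) term does not involve the parameters)
    return float(-0.5 * np.sum(dev / phi + np.log(phi)))


def dglm_fit(y: np.ndarray, spec: DGLMSpec) -> DGLMFit:
    """Fit a double GLM by alternating mean and dispersion submodels."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("y must be finite")
    Xm, Xd = spec.mean_design, spec.disp_design
    if len(y) != Xm.shape[0]:
        raise ValidationError("response length disagrees with design")
    if spec.family == "poisson":
        if np.any(y < 0) or np.any(y != np.rint(y)):
            raise ValidationError("Poisson family requires non-negative integer y")
        return _dglm_fit_poisson(y, spec)
    return _dglm_fit_gaussian(y, spec)


def _check_disp_eta(eta_d: np.ndarray) -> None:
    if np.max(np.abs(eta_d)) > ETA_LIMIT:
        raise DivergenceError("dispersion linear predictor overflow (|eta| > 700)")


def _dglm_fit_gaussian(y: np.ndarray, spec: DGLMSpec) -> DGLMFit:
    Xm, Xd = spec.mean_design, spec.disp_design
    n, p_m = Xm.shape
    w = np.ones(n)
    beta = lam = None
    lam_cov = beta_cov = None
    h = None
    warnings: list[str] = []
    converged = False
    prev_loglik = -np.inf
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        new_beta, beta_cov = wls(Xm, y, w)
        h = leverages_from_factor(Xm, beta_cov, w)
        e = y - Xm @ new_beta
        d = e * e / (1.0 - h)
        d = np.maximum(d, 1e-300)
        prior = (1.0 - h) / 2.0
        new_lam, lam_cov, _ = gamma_glm_log(d, Xd, prior, start=lam)
        eta_d = Xd @ new_lam
        _check_disp_eta(eta_d)
        sigma2 = np.exp(eta_d)
        w = 1.0 / sigma2
        if beta is not None:
            delta = max(
                np.max(np.abs(new_beta - beta) / (1.0 + np.abs(beta))),
                np.max(np.abs(new_lam - lam) / (1.0 + np.abs(lam))),
            )
            if delta < spec.tol:
                beta, lam = new_beta, new_lam
                converged = True
                break
        ll = _gaussian_loglik(e, sigma2)
        if ll < prev_loglik - 1e-6:
            warnings.append("loglik_decreased")
        prev_loglik = ll
        beta, lam = new_beta, new_lam
    if not converged:
        warnings.append("max_iter_reached")
    # final consistent state: refit the mean at the converged weights
    beta, beta_cov = wls(Xm, y, w)
    h = leverages_from_factor(Xm, beta_cov, w)
    e = y - Xm @ beta
    sigma2 = np.exp(Xd @ lam)
    return DGLMFit(
        beta=beta, lam=lam, sigma2=sigma2, leverages=h,
        loglik=_gaussian_loglik(e, sigma2), n_iter=n_iter, converged=converged,
        beta_cov=beta_cov, lam_cov=lam_cov, fitted_mean=Xm @ beta,
        family="gaussian", warnings=warnings,
    )


def _dglm_fit_poisson(y: np.ndarray, spec: DGLMSpec) -> DGLMFit:
    Xm, Xd = spec.mean_design, spec.disp_design
    n, p_m = Xm.shape
    phi = np.ones(n)
    beta = lam = None
    lam_cov = beta_cov = None
    warnings: list[str] = []
    converged = False
    n_iter = 0
    mu = None
    h = None
    for n_iter in range(1, spec.max_iter + 1):
        new_beta, beta_cov, mu, w_work, _ = poisson_glm_log(
            y, Xm, prior_weights=1.0 / phi, start=beta
        )
        h = leverages_from_factor(Xm, beta_cov, w_work)
        dev = _poisson_unit_deviance(y, mu)
        d = np.maximum(dev, 1e-10) / (1.0 - h)
        prior = (1.0 - h) / 2.0
        new_lam, lam_cov, _ = gamma_glm_log(d, Xd, prior, start=lam)
        eta_d = Xd @ new_lam
        _check_disp_eta(eta_d)
        phi = np.exp(eta_d)
        if beta is not None:
            delta = max(
                np.max(np.abs(new_beta - beta) / (1.0 + np.abs(beta))),
                np.max(np.abs(new_lam - lam) / (1.0 + np.abs(lam))),
            )
            if delta < spec.tol:
                beta, lam = new_beta, new_lam
                converged = True
                break
        beta, lam = new_beta, new_lam
    if not converged:
        warnings.append("max_iter_reached")
    dev = _poisson_unit_deviance(y, mu)
    return DGLMFit(
        beta=beta, lam=lam, sigma2=phi, leverages=h,
        loglik=_poisson_eql(dev, phi), n_iter=n_iter, converged=converged,
        beta_cov=beta_cov, lam_cov=lam_cov, fitted_mean=mu,
        family="poisson", warnings=warnings,
    )


def _design(n: int, covariates: np.ndarray | None, g: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    if g is not None:
        cols.append(np.asarray(g, dtype=float))
    return np.column_stack(cols)


def dglm_vqtl_test(
    y: np.ndarray,
    covariates: np.ndarray | None,
    g: np.ndarray,
    family: str = "gaussian",
    test: str = "lrt",
    marker_id: str = "",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> VQTLTestResult:
    """Test a marker for a variance (dispersion) effect with a DGLM.

    Full model: mean design [1, covariates, g], dispersion design [1, g].
    Null model: same mean design, intercept-only dispersion, so the test
    isolates the variance effect of the genotype. ``test='lrt'`` compares
    twice the log-likelihood (or EQL) gap to chi^2(1); ``'wald'`` refers
    lambda_g / se to the standard normal. The mean-effect test is read
    off the full model's mean submodel.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.all(g == g[0]):
        raise MonomorphicError("genotype dosage is constant")
    if test not in ("lrt", "wald"):
        raise ValueError(f"unknown test {test!r}")
    n = len(y)
    Xm = _design(n, covariates, g)
    Xd_full = _design(n, None, g)
    Xd_null = _design(n, None, None)

    full = dglm_fit(y, DGLMSpec(family, Xm, Xd_full, max_iter=max_iter, tol=tol))
    warnings = list(full.warnings)
    disp_beta = float(full.lam[-1])
    disp_se = float(np.sqrt(full.lam_cov[-1, -1]))
    if test == "lrt":
        null = dglm_fit(y, DGLMSpec(family, Xm, Xd_null, max_iter=max_iter, tol=tol))
        warnings += [w for w in null.warnings if w not in warnings]
        stat = 2.0 * (full.loglik - null.loglik)
        if stat < -1e-8:
            warnings.append("negative_lrt_floored")
        stat = max(stat, 0.0)
        disp_p = float(stats.chi2.sf(stat, 1))
        converged = full.converged and null.converged
    else:
        z = disp_beta / disp_se
        stat = z * z
        disp_p = float(2.0 * stats.norm.sf(abs(z)))
        converged = full.converged

    # mean-effect test from the full model's mean submodel (genotype is
    # the last mean-design column)
    mean_beta = float(full.beta[-1])
    if family == "gaussian":
        mean_se = float(np.sqrt(full.beta_cov[-1, -1]))
    else:
        mean_se = float(np.sqrt(full.beta_cov[-1, -1]))
    mean_z = mean_beta / mean_se
    mean_p = float(2.0 * stats.norm.sf(abs(mean_z)))

    if not converged:
        warnings.append("non_converged_fit")
    return VQTLTestResult(
        marker_id=marker_id, method="dglm", n_used=n,
        mean_beta=mean_beta, mean_se=mean_se, mean_p=mean_p,
        disp_beta=disp_beta, disp_se=disp_se,
        disp_stat=float(stat), disp_df=1.0, disp_p=disp_p,
        converged=converged, warnings=warnings,
    )
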