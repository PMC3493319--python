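"""Two-stage variance-heterogeneity tests (SVLM and relatives).

These approximate the joint DGLM by conditioning on a first-stage mean
fit: stage 1 regresses the trait on the usual GWAS design (intercept,
covariates, and by default the SNP dosage); stage 2 then regresses a
function of the stage-1 residuals on the dosage. Variants differ only in
stage 2:

* ``normal_sq``  - least squares on squared residuals (SVLM);
* ``gamma_sq``   - log-link gamma GLM on squared residuals;
* ``normal_abs`` - least squares on absolute residuals.

None of these account for the estimation error of the residuals; the
``hat_screen`` diagnostic checks the stage-1 leverages, which bound the
influence of that error — if all hat values are small (< 0.05 by
default) the shortcut is safe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import VQTLTestResult
from .errors import DegenerateFitError, MonomorphicError, ValidationError
from .glmfit import gamma_glm_log, wls
from .dglm import leverages

__all__ = [
    "TwoStageConfig",
    "HatScreenReport",
    "svlm_test",
    "hat_screen",
    "pvalue_concordance",
]

STAGE2_VARIANTS = ("normal_sq", "gamma_sq", "normal_abs")
_METHOD_LABEL = {"normal_sq": "svlm", "gamma_sq": "svlm_gamma", "normal_abs": "absres"}


@dataclass
class TwoStageConfig:
    """Stage composition of a two-stage test.

    stage1_includes_snp : include the dosage in the stage-1 mean model
        (an ordinary GWAS model contains the SNP); disable to reproduce
        covariates-only pre-correction.
    stage2 : which residual transform/model to use in stage 2.
    stage2_includes_covariates : carry the covariates into stage 2 as
        well (off by default — they were already removed in stage 1).
    """

    stage1_includes_snp: bool = True
    stage2: str = "normal_sq"
    stage2_includes_covariates: bool = False

    def __post_init__(self) -> None:
        if self.stage2 not in STAGE2_VARIANTS:
            raise ValidationError(f"unknown stage-2 variant {self.stage2!r}")


@dataclass
class HatScreenReport:
    max_leverage: float
    flagged: np.ndarray  # indices with h_ii >= threshold
    threshold: float
    passed: bool


def _stack(n: int, covariates: np.ndarray | None, g: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    if g is not None:
        cols.append(np.asarray(g, dtype=float))
    return np.column_stack(cols)


def _ols_t(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS with classical t-test machinery: (beta, se, resid, df)."""
    beta, XtX_inv = wls(X, y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    if df < 1:
        raise ValidationError("not enough residual degrees of freedom")
    s2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
    return beta, se, resid, df


def svlm_test(
    y: np.ndarray,
    covariates: np.ndarray | None,
    g: np.ndarray,
    config: TwoStageConfig | None = None,
    marker_id: str = "",
) -> VQTLTestResult:
    """Two-stage variance test of a marker (SVLM by default)."""
    if config is None:
        config = TwoStageConfig()
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.all(g == g[0]):
        raise MonomorphicError("genotype dosage is constant")
    n = len(y)
    warnings: list[str] = []

    X1 = _stack(n, covariates, g if config.stage1_includes_snp else None)
    beta1, se1, resid, df1 = _ols_t(X1, y)
    if np.max(np.abs(resid)) < 1e-12:
        raise DegenerateFitError("stage-1 fit is saturated (zero residuals)")

    mean_beta = mean_se = mean_p = np.nan
    if config.stage1_includes_snp:
        mean_beta = float(beta1[-1])
        mean_se = float(se1[-1])
        mean_p = float(2.0 * stats.t.sf(abs(mean_beta / mean_se), df1))

    X2 = _stack(n, covariates if config.stage2_includes_covariates else None, g)
    df2 = n - X2.shape[1]

    if config.stage2 == "gamma_sq":
        r2 = resid * resid
        if np.any(r2 == 0):
            r2 = np.maximum(r2, 1e-12)
            warnings.append("zero_squared_residual_floored")
        coef, cov_unit, converged = gamma_glm_log(r2, X2)
        mu = np.exp(X2 @ coef)
        # moment (Pearson) estimate of the gamma dispersion scales the covariance
        phi = float(np.sum((r2 - mu) ** 2 / mu**2)) / df2
        disp_beta = float(coef[-1])
        disp_se = float(np.sqrt(phi * cov_unit[-1, -1]))
        z = disp_beta / disp_se
        stat = z * z
        disp_p = float(2.0 * stats.norm.sf(abs(z)))
        if not converged:
            warnings.append("non_converged_fit")
    else:
        response = resid * resid if config.stage2 == "normal_sq" else np.abs(resid)
        beta2, se2, resid2, df2 = _ols_t(X2, response)
        disp_beta = float(beta2[-1])
        disp_se = float(se2[-1])
        scale = max(float(np.mean(response * response)), 1e-300)
        if float(resid2 @ resid2) / df2 <= 1e-24 * scale:
            # stage-2 response is (numerically) an exact linear function of
            # the design — for a constant response this means no variance
            # signal at all, so report a null result rather than 0/0
            stat, disp_p = 0.0, 1.0
            disp_beta = 0.0 if abs(disp_beta) < 1e-10 else disp_beta
            warnings.append("degenerate_stage2_fit")
        else:
            t = disp_beta / disp_se
            stat = t * t
            disp_p = float(2.0 * stats.t.sf(abs(t), df2))
        converged = True

    return VQTLTestResult(
        marker_id=marker_id, method=_METHOD_LABEL[config.stage2], n_used=n,
        mean_beta=mean_beta, mean_se=mean_se, mean_p=mean_p,
        disp_beta=disp_beta, disp_se=disp_se,
        disp_stat=float(stat), disp_df=1.0, disp_p=disp_p,
        converged=bool(converged), warnings=warnings,
    )


def hat_screen(X: np.ndarray, threshold: float = 0.05) -> HatScreenReport:
    """Leverage screen for the stage-1 (standard GWAS) design.

    The expected squared residual understates the true one by the factor
    1 - h_ii, so large hat values signal that two-stage output cannot be
    trusted. The screen passes when every h_ii is below ``threshold``.
    """
    h = leverages(np.asarray(X, dtype=float))
    flagged = np.flatnonzero(h >= threshold)
    return HatScreenReport(
        max_leverage=float(h.max()),
        flagged=flagged,
        threshold=float(threshold),
        passed=flagged.size == 0,
    )


def pvalue_concordance(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Pearson correlation of two aligned p-value vectors."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape or p_a.ndim != 1 or len(p_a) < 3:
        raise ValidationError("need two equal-length p-value vectors of length >= 3")
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if np.any((p < 0) | (p > 1)):
            raise ValidationError(f"{name} contains values outside [0, 1]")
        if np.ptp(p) == 0:
            raise ValidationError(f"{name} has zero variance; correlation undefined")
    return float(np.corrcoef(p_a, p_b)[0, 1])
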