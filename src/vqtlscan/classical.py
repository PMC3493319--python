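"""Group-based non-parametric variance-heterogeneity tests.

Each genotype class is treated as a group and classical tests of variance
homogeneity are applied: Levene's test (an ANOVA F-test on absolute
deviations from the group center, with mean or median centering) and the
Fligner-Killeen normal-scores rank test. These tests are robust to
distributional misspecification but cannot model continuous covariates or
fractional dosages, so dosages are first rounded to hard genotype classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import VQTLTestResult
from .errors import MonomorphicError, ValidationError

__all__ = [
    "GroupedTrait",
    "GroupSummary",
    "dosage_to_groups",
    "levene_test",
    "fligner_killeen_test",
    "group_summary",
]


@dataclass
class GroupedTrait:
    """Trait values partitioned into k >= 2 genotype classes.

    Groups with fewer than two observations cannot contribute a variance
    estimate and are excluded at construction (recorded in ``warnings``);
    if fewer than two groups remain, the trait is effectively monomorphic
    and an error is raised.
    """

    values: np.ndarray
    group_labels: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels)
        if self.values.shape != self.group_labels.shape or self.values.ndim != 1:
            raise ValidationError("values and group_labels must be equal-length vectors")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trait values must be finite")
        labels, counts = np.unique(self.group_labels, return_counts=True)
        small = labels[counts < 2]
        if small.size:
            keep = ~np.isin(self.group_labels, small)
            self.values = self.values[keep]
            self.group_labels = self.group_labels[keep]
            self.warnings.append(
                f"dropped_small_groups:{','.join(str(s) for s in small)}"
            )
            labels, counts = np.unique(self.group_labels, return_counts=True)
        if labels.size < 2:
            raise MonomorphicError(
                "fewer than two genotype classes with n >= 2 observations"
            )
        self.group_ids = labels
        self.group_sizes = counts

    @property
    def k(self) -> int:
        return len(self.group_ids)

    @property
    def n(self) -> int:
        return len(self.values)

    def groups(self) -> list[np.ndarray]:
        return [self.values[self.group_labels == g] for g in self.group_ids]


@dataclass
class GroupSummary:
    """Per-genotype-class descriptive statistics.

    The coefficient of variation (sd/mean) is meaningful only for
    positive-valued traits; it is flagged undefined where the group mean
    is not positive.
    """

    group_ids: np.ndarray
    n: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    cv_defined: np.ndarray


def dosage_to_groups(dosages: np.ndarray) -> tuple[np.ndarray, int]:
    """Round dosages to hard genotype classes {0, 1, 2}.

    Uses round-half-to-even so that 0.5 dosages map deterministically.
    Returns the labels and the count of clearly fractional dosages
    (|dosage - round| > 0.1), which callers should surface as a warning:
    group-based tests discard the information in genotype probabilities.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
        raise ValidationError("dosages must lie in [0, 2]")
    labels = np.rint(dosages).astype(int)
    n_fractional = int(np.sum(np.abs(dosages - labels) > 0.1))
    if len(np.unique(labels)) < 2:
        raise MonomorphicError("marker is monomorphic after rounding to classes")
    return labels, n_fractional


def _grouped_result(
    marker_id: str, method: str, grouped: GroupedTrait,
    stat: float, df: float, p: float, warnings: list[str],
) -> VQTLTestResult:
    return VQTLTestResult(
        marker_id=marker_id, method=method, n_used=grouped.n,
        disp_stat=float(stat), disp_df=float(df), disp_p=float(p),
        warnings=list(grouped.warnings) + warnings,
    )


def levene_test(
    grouped: GroupedTrait, center: str = "mean", marker_id: str = ""
) -> VQTLTestResult:
    """Levene's test for variance homogeneity across genotype classes.

    Computes z_ij = |y_ij - c_j| with c_j the group mean (``center='mean'``,
    the classical form) or median (``'median'``, the Brown-Forsythe
    variant), then the one-way ANOVA F statistic on z:

        W = [(N-k)/(k-1)] * sum_j n_j (zbar_j - zbar)^2
                           / sum_ij (z_ij - zbar_j)^2

    compared against F(k-1, N-k).
    """
    if center not in ("mean", "median"):
        raise ValueError(f"unknown centering {center!r}")
    k, n = grouped.k, grouped.n
    if n - k < 1:
        raise ValidationError("need N - k >= 1 residual degrees of freedom")
    warnings: list[str] = []
    z_groups = []
    for vals in grouped.groups():
        c = vals.mean() if center == "mean" else np.median(vals)
        z_groups.append(np.abs(vals - c))
    z_all = np.concatenate(z_groups)
    # deviations that are pure roundoff relative to the data scale are zero
    scale = max(1.0, float(np.max(np.abs(grouped.values))))
    if z_all.max() <= 1e-12 * scale:
        return _grouped_result(
            marker_id, "levene", grouped, 0.0, k - 1, 1.0,
            warnings + ["degenerate_deviations"],
        )
    grand = z_all.mean()
    between = sum(len(z) * (z.mean() - grand) ** 2 for z in z_groups)
    within = sum(((z - z.mean()) ** 2).sum() for z in z_groups)
    if within <= 0:
        if between <= 0:
            # every deviation identical: no evidence either way
            stat, p = 0.0, 1.0
        else:
            # deviations constant within groups but different between them
            stat, p = float("inf"), 0.0
        warnings.append("degenerate_deviations")
    else:
        stat = (n - k) / (k - 1) * between / within
        p = float(stats.f.sf(stat, k - 1, n - k))
    return _grouped_result(marker_id, "levene", grouped, stat, k - 1, p, warnings)


def fligner_killeen_test(grouped: GroupedTrait, marker_id: str = "") -> VQTLTestResult:
    """Fligner-Killeen normal-scores test for variance homogeneity.

    Ranks |y_ij - median_j| across all N observations (midranks for
    ties), converts ranks to normal scores a(r) = Phi^{-1}(1/2 + r/(2(N+1))),
    and compares X^2 = sum_j n_j (Abar_j - abar)^2 / V^2 to chi^2(k-1),
    where abar and V^2 are the grand mean and sample variance of the
    scores. Being rank-based, the statistic is invariant under positive
    scaling of the trait.
    """
    k, n = grouped.k, grouped.n
    warnings: list[str] = []
    devs = []
    for vals in grouped.groups():
        devs.append(np.abs(vals - np.median(vals)))
    dev_all = np.concatenate(devs)
    scale = max(1.0, float(np.max(np.abs(grouped.values))))
    if dev_all.max() <= 1e-12 * scale:
        return _grouped_result(
            marker_id, "fligner", grouped, 0.0, k - 1, 1.0, ["degenerate_deviations"]
        )
    ranks = stats.rankdata(dev_all, method="average")
    scores = stats.norm.ppf(0.5 + ranks / (2.0 * (n + 1)))
    grand = scores.mean()
    v2 = scores.var(ddof=1)
    stat = 0.0
    offset = 0
    for vals in grouped.groups():
        nj = len(vals)
        stat += nj * (scores[offset:offset + nj].mean() - grand) ** 2
        offset += nj
    stat /= v2
    p = float(stats.chi2.sf(stat, k - 1))
    return _grouped_result(marker_id, "fligner", grouped, stat, k - 1, p, warnings)


def group_summary(grouped: GroupedTrait) -> GroupSummary:
    """n, mean, unbiased variance, sd, and CV per genotype class."""
    means, variances = [], []
    for vals in grouped.groups():
        means.append(vals.mean())
        variances.append(vals.var(ddof=1))
    means = np.array(means)
    variances = np.array(variances)
    sds = np.sqrt(variances)
    defined = means > 0
    cv = np.where(defined, sds / np.where(defined, means, 1.0), np.nan)
    return GroupSummary(
        group_ids=grouped.group_ids, n=grouped.group_sizes,
        mean=means, variance=variances, sd=sds, cv=cv, cv_defined=defined,
    )
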