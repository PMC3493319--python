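"""Core data containers and sample alignment.

The universal genotype representation is the allele dosage: the expected
count of the alternate allele per individual, a real number in [0, 2].
Hard genotype calls are the integer special case; imputed genotype
probabilities collapse to fractional dosages, which the regression-based
tests accept directly as predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "VQTLTestResult",
    "align",
]


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-dosage matrix.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (rows).
    marker_ids
        Ordered, unique marker identifiers (columns).
    dosages
        ``(n_samples, n_markers)`` array of expected alternate-allele
        counts in ``[0, 2]``; fractional values represent imputed or
        probabilistic genotypes.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.marker_ids):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("marker_ids are not unique")
        if not np.all(np.isfinite(self.dosages)):
            raise ValidationError("dosages contain non-finite values")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            bad = np.argwhere((self.dosages < 0) | (self.dosages > 2))[0]
            raise ValidationError(
                f"dosage out of range [0, 2] at sample "
                f"{self.sample_ids[bad[0]]!r}, marker {self.marker_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker(self, marker_id: str) -> np.ndarray:
        """Dosage vector for one marker."""
        j = self.marker_ids.index(marker_id)
        return self.dosages[:, j]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.marker_ids), self.dosages[rows])


@dataclass
class PhenotypeTable:
    """Per-sample trait value with optional covariate columns."""

    sample_ids: list[str]
    trait: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.trait = np.asarray(self.trait, dtype=float)
        if self.trait.ndim != 1 or len(self.trait) != len(self.sample_ids):
            raise ValidationError("trait length must equal number of samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        if self.covariates is None or len(self.covariates) == 0:
            self.covariates = pd.DataFrame(index=range(len(self.sample_ids)))
        if len(self.covariates) != len(self.sample_ids):
            raise ValidationError("covariate rows must equal number of samples")
        self.covariates = self.covariates.reset_index(drop=True)
        for col in self.covariates.columns:
            vals = self.covariates[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size > 1 and np.all(finite == finite[0]) and finite.size == vals.size:
                raise ValidationError(
                    f"covariate {col!r} is constant (duplicates the intercept)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Covariate columns as a float matrix (n x c); empty names -> (n, 0)."""
        if names is None:
            names = list(self.covariates.columns)
        if not names:
            return np.empty((self.n_samples, 0))
        return self.covariates[list(names)].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return PhenotypeTable(
            list(sample_ids),
            self.trait[rows],
            self.covariates.iloc[rows].reset_index(drop=True),
        )


@dataclass
class VQTLTestResult:
    """Per-marker output of a vQTL test.

    ``mean_*`` fields describe the genotype effect on the trait mean and
    ``disp_*`` fields the effect on its dispersion. Group-based tests
    (Levene, Fligner-Killeen) report only the dispersion statistic; the
    coefficient fields stay NaN for them.
    """

    marker_id: str
    method: str
    n_used: int
    mean_beta: float = np.nan
    mean_se: float = np.nan
    mean_p: float = np.nan
    disp_beta: float = np.nan
    disp_se: float = np.nan
    disp_stat: float = np.nan
    disp_df: float = np.nan
    disp_p: float = np.nan
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    VALID_METHODS = ("levene", "fligner", "svlm", "svlm_gamma", "absres", "dglm")

    def __post_init__(self) -> None:
        if self.method not in self.VALID_METHODS:
            raise ValidationError(f"unknown method label {self.method!r}")
        for name in ("mean_p", "disp_p"):
            p = getattr(self, name)
            if np.isfinite(p) and not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if np.isfinite(self.disp_stat) and self.disp_stat < 0:
            raise ValidationError("disp_stat must be non-negative")
        if np.isfinite(self.disp_df) and self.disp_df < 1:
            raise ValidationError("disp_df must be >= 1")


def align(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    na_policy: str = "drop",
) -> tuple[GenotypeMatrix, PhenotypeTable, int]:
    """Restrict both objects to their shared samples, in phenotype order.

    Samples with a missing trait or covariate value are dropped
    (``na_policy='drop'``, listwise deletion) or rejected
    (``na_policy='error'``). Returns the aligned pair and the number of
    samples dropped relative to the phenotype table.

    Ordering follows the phenotype file so that downstream fits are
    deterministic regardless of genotype file ordering.
    """
    if na_policy not in ("drop", "error"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    geno_ids = set(genotypes.sample_ids)
    shared = [s for s in phenotypes.sample_ids if s in geno_ids]
    if not shared:
        raise AlignmentError("no samples shared between genotypes and phenotypes")

    pheno = phenotypes.subset_samples(shared)
    complete = np.isfinite(pheno.trait)
    if pheno.covariates.shape[1]:
        complete &= np.all(np.isfinite(pheno.covariates.to_numpy(dtype=float)), axis=1)
    if not complete.all():
        if na_policy == "error":
            bad = [s for s, ok in zip(pheno.sample_ids, complete) if not ok]
            raise AlignmentError(f"missing trait/covariate values for samples {bad}")
        shared = [s for s, ok in zip(pheno.sample_ids, complete) if ok]
        if not shared:
            raise AlignmentError("all shared samples have missing values")
        pheno = pheno.subset_samples(shared)

    n_dropped = phenotypes.n_samples - len(shared)
    return genotypes.subset_samples(shared), pheno, n_dropped
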