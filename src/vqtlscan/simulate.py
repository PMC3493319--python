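"""Generators for the three benchmark scenarios.

All scenarios draw genotypes independently as g ~ Bin(2, 0.4) — a
biallelic marker in Hardy-Weinberg proportions with alternate-allele
frequency 0.4 — for n individuals (default 10,000):

* ``interaction_vqtl`` — a true vQTL produced by an unobserved
  interacting factor: F ~ N(0, 1) and
  y ~ N(beta_F * F + beta_gF * g * F, 1) with beta_F = 0.85 and
  beta_gF = 0.06. Marginally over F, Var(y | g) = 1 + (beta_F +
  beta_gF * g)^2 increases with dosage while E(y | g) = 0: a pure
  variance signal. F is retained on the dataset for truth-checking but
  is never passed to the tests, mirroring the premise that the
  interacting factor is unmeasured.

* ``gaussian_null`` — y ~ N(0, 1) independent of g; no mean or variance
  effect. Calibration baseline.

* ``poisson_null`` — y ~ Poisson(exp(mu + beta_g * g)) with mu = -1 and
  beta_g = 0.05: a genotype effect on the mean whose variance tracks the
  mean only through the Poisson law. Not a vQTL — any dispersion-test
  rejection is a scale/misspecification artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import GenotypeMatrix, PhenotypeTable
from .errors import ValidationError

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "simulate_interaction",
    "simulate_gaussian_null",
    "simulate_poisson_null",
    "simulate_scenario",
    "dataset_to_tables",
]

SCENARIOS = ("interaction_vqtl", "gaussian_null", "poisson_null")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated dataset.

    Defaults are the benchmark study conditions: n = 10,000 individuals,
    allele frequency q = 0.4, main factor effect beta_F = 0.85,
    interaction beta_gF = 0.06, Poisson intercept mu = -1 and genotype
    mean effect beta_g = 0.05. Parameters not used by a scenario are
    ignored there.
    """

    scenario: str
    n: int = 10_000
    q: float = 0.4
    beta_F: float = 0.85
    beta_gF: float = 0.06
    mu: float = -1.0
    beta_g: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.n < 10:
            raise ValidationError("n must be >= 10")
        if not 0.0 < self.q < 1.0:
            raise ValidationError("allele frequency q must be in (0, 1)")


@dataclass
class SimulatedDataset:
    """One simulated trait/genotype draw.

    ``F`` is the latent interacting factor (None outside the interaction
    scenario); it exists only for truth-checking and must never be fed
    to the tests. ``has_vqtl``/``has_mean_effect`` record the generating
    truth.
    """

    y: np.ndarray
    g: np.ndarray
    F: np.ndarray | None
    has_vqtl: bool
    has_mean_effect: bool
    config: ScenarioConfig


def _draw_genotypes(rng: np.random.Generator, n: int, q: float) -> np.ndarray:
    return rng.binomial(2, q, size=n).astype(float)


def simulate_interaction(config: ScenarioConfig) -> SimulatedDataset:
    """Genotype-by-latent-factor interaction manifesting as a vQTL."""
    if config.scenario != "interaction_vqtl":
        raise ValidationError("config.scenario must be 'interaction_vqtl'")
    rng = np.random.default_rng(config.seed)
    g = _draw_genotypes(rng, config.n, config.q)
    F = rng.normal(size=config.n)
    y = rng.normal(loc=config.beta_F * F + config.beta_gF * g * F, scale=1.0)
    return SimulatedDataset(
        y=y, g=g, F=F,
        has_vqtl=config.beta_gF != 0.0, has_mean_effect=False, config=config,
    )


def simulate_gaussian_null(config: ScenarioConfig) -> SimulatedDataset:
    """Standard-normal trait independent of genotype."""
    if config.scenario != "gaussian_null":
        raise ValidationError("config.scenario must be 'gaussian_null'")
    rng = np.random.default_rng(config.seed)
    g = _draw_genotypes(rng, config.n, config.q)
    y = rng.normal(size=config.n)
    return SimulatedDataset(
        y=y, g=g, F=None, has_vqtl=False, has_mean_effect=False, config=config
    )


def simulate_poisson_null(config: ScenarioConfig) -> SimulatedDataset:
    """Poisson counts with a genotype mean effect and no vQTL."""
    if config.scenario != "poisson_null":
        raise ValidationError("config.scenario must be 'poisson_null'")
    rng = np.random.default_rng(config.seed)
    g = _draw_genotypes(rng, config.n, config.q)
    y = rng.poisson(np.exp(config.mu + config.beta_g * g)).astype(float)
    return SimulatedDataset(
        y=y, g=g, F=None,
        has_vqtl=False, has_mean_effect=config.beta_g != 0.0, config=config,
    )


_DISPATCH = {
    "interaction_vqtl": simulate_interaction,
    "gaussian_null": simulate_gaussian_null,
    "poisson_null": simulate_poisson_null,
}


def simulate_scenario(config: ScenarioConfig, trial: int | None = None) -> SimulatedDataset:
    """Simulate one dataset; ``trial`` derives a per-trial seed as seed + trial."""
    if trial is not None:
        config = replace(config, seed=config.seed + trial)
    return _DISPATCH[config.scenario](config)


def dataset_to_tables(
    data: SimulatedDataset, marker_id: str = "sim1"
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Package a simulated draw as the standard genotype/phenotype pair."""
    ids = [f"S{i + 1}" for i in range(len(data.y))]
    genotypes = GenotypeMatrix(ids, [marker_id], data.g[:, None])
    phenotypes = PhenotypeTable(ids, data.y)
    return genotypes, phenotypes
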