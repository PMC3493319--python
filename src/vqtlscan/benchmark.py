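"""Monte-Carlo study runner: false-positive rates, power, concordance.

Each trial simulates one dataset and applies every requested method to
that same dataset (a paired design), so between-method comparisons are
free of simulation noise. Per-trial seeds are derived deterministically
from the study seed (seed + trial index), making studies reproducible
and resumable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classical import GroupedTrait, dosage_to_groups, fligner_killeen_test, levene_test
from .dglm import dglm_vqtl_test
from .errors import ConfigurationError
from .simulate import ScenarioConfig, SimulatedDataset, simulate_scenario
from .twostage import TwoStageConfig, pvalue_concordance, svlm_test

__all__ = ["StudyResult", "run_study", "run_power_study", "METHODS"]

#: fraction of non-converged fits above which a study is flagged
NONCONVERGENCE_FLAG_RATE = 0.02


@dataclass
class StudyResult:
    """Rejection behaviour of one method over a Monte-Carlo study."""

    method: str
    scenario: str
    trials: int
    alpha: float
    rejection_rate: float
    mc_se: float
    pvalues: np.ndarray
    n_nonconverged: int = 0
    flagged: bool = False

    def rejection_rate_at(self, alpha: float) -> float:
        """Rejection rate at another level, from the stored p-values."""
        return float(np.mean(self.pvalues < alpha))


def _run_levene(data: SimulatedDataset, center: str = "mean") -> float:
    labels, _ = dosage_to_groups(data.g)
    return levene_test(GroupedTrait(data.y, labels), center=center).disp_p


def _run_fligner(data: SimulatedDataset) -> float:
    labels, _ = dosage_to_groups(data.g)
    return fligner_killeen_test(GroupedTrait(data.y, labels)).disp_p


# The benchmark's Levene defaults to median centering (Brown-Forsythe):
# on the Poisson-null scenario only the median-centered variant shows the
# published rejection behaviour, and median centering is also the default
# of the widely used R implementation (car::leveneTest). levene_test()
# itself keeps the classical mean centering as its default; pass
# levene_center="mean" to benchmark that variant instead.
METHODS = {
    "levene": lambda d, opt: _run_levene(d, center=opt.get("levene_center", "median")),
    "fligner": lambda d, opt: _run_fligner(d),
    "svlm": lambda d, opt: svlm_test(d.y, None, d.g, TwoStageConfig(stage2="normal_sq")),
    "svlm_gamma": lambda d, opt: svlm_test(d.y, None, d.g, TwoStageConfig(stage2="gamma_sq")),
    "dglm_gaussian": lambda d, opt: dglm_vqtl_test(
        d.y, None, d.g, family="gaussian", test=opt.get("dglm_test", "lrt")
    ),
    "dglm_poisson": lambda d, opt: dglm_vqtl_test(
        d.y, None, d.g, family="poisson", test=opt.get("dglm_test", "lrt")
    ),
}


def run_study(
    config: ScenarioConfig,
    methods: list[str],
    trials: int = 1000,
    alpha: float = 0.05,
    **options,
) -> list[StudyResult]:
    """Run a paired Monte-Carlo study of the requested methods.

    Non-converged fits contribute their returned p-value but are
    counted; a method whose non-convergence fraction exceeds 2% of
    trials is flagged on its :class:`StudyResult`.
    """
    if trials < 1:
        raise ConfigurationError("trials must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError("alpha must be in (0, 1]")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ConfigurationError(f"unknown methods {unknown}")
    if "dglm_poisson" in methods and config.scenario != "poisson_null":
        raise ConfigurationError(
            "dglm_poisson requires integer count traits; "
            f"scenario {config.scenario!r} generates a continuous trait"
        )

    pvals = {m: np.empty(trials) for m in methods}
    nonconv = {m: 0 for m in methods}
    for trial in range(trials):
        data = simulate_scenario(config, trial=trial)
        for m in methods:
            out = METHODS[m](data, options)
            if isinstance(out, float):
                pvals[m][trial] = out
            else:
                pvals[m][trial] = out.disp_p
                if not out.converged:
                    nonconv[m] += 1

    results = []
    for m in methods:
        r = float(np.mean(pvals[m] < alpha))
        results.append(StudyResult(
            method=m, scenario=config.scenario, trials=trials, alpha=alpha,
            rejection_rate=r, mc_se=float(np.sqrt(r * (1.0 - r) / trials)),
            pvalues=pvals[m], n_nonconverged=nonconv[m],
            flagged=nonconv[m] > NONCONVERGENCE_FLAG_RATE * trials,
        ))
    return results


def run_power_study(
    config: ScenarioConfig | None = None,
    methods: list[str] | None = None,
    trials: int = 1000,
    alpha: float = 0.05,
    **options,
) -> tuple[list[StudyResult], float | None]:
    """Power study on the interaction scenario, plus SVLM-DGLM concordance.

    Returns the per-method study results and, when both ``svlm`` and
    ``dglm_gaussian`` are among the methods, the Pearson correlation of
    their per-trial p-values.
    """
    if config is None:
        config = ScenarioConfig(scenario="interaction_vqtl")
    if config.scenario != "interaction_vqtl":
        raise ConfigurationError("power study runs on the interaction_vqtl scenario")
    if methods is None:
        methods = ["levene", "svlm", "dglm_gaussian"]
    results = run_study(config, methods, trials=trials, alpha=alpha, **options)
    by_method = {r.method: r for r in results}
    concordance = None
    if "svlm" in by_method and "dglm_gaussian" in by_method:
        concordance = pvalue_concordance(
            by_method["svlm"].pvalues, by_method["dglm_gaussian"].pvalues
        )
    return results, concordance
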