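"""Synthetic communities, ground-truth webs and under-sampled observations.

Real body-mass datasets for whole communities span many orders of magnitude
(from unicellular producers below 1e-8 g to top predators above 1e5 g), so
communities are generated with log-uniform masses over a configurable
log10 range. Ground-truth webs are produced by the ADBM itself under known
parameters, which makes every stage of the fitting pipeline testable with a
known answer. Under-sampling of real food webs is emulated by deleting each
observed link independently with probability q.

The packaged default scenario (S = 20 species, masses log-uniform over
1e-6 to 1e2 g, log10 a = -3, ai = aj = 0.5, b = 0.1, q = 0.2) lives in
``adbm/data/default_scenario.json`` so that benchmarks share one baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .fit import (
    ABCConfig,
    PriorSpec,
    posterior_predictive,
    rejection_abc,
    select_threshold,
    summarize_posterior,
)
from .model import ADBMParams, predict_web
from .tss import confusion_counts, true_skill_statistic
from .webio import Community, PredationMatrix, connectance

__all__ = [
    "SyntheticScenario",
    "RecoveryReport",
    "default_scenario",
    "generate_community",
    "generate_truth",
    "degrade_web",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully specified synthetic benchmark instance."""

    S: int
    log10_mass_bounds: tuple[float, float]
    true_params: ADBMParams
    removal_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.S < 2:
            raise ValueError("S must be >= 2")
        lo, hi = self.log10_mass_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("log10_mass_bounds must be a finite increasing interval")
        if not (0 <= self.removal_prob <= 1):
            raise ValueError("removal_prob must be in [0, 1]")


def default_scenario(seed: int | None = None) -> SyntheticScenario:
    """Load the packaged default scenario, optionally overriding its seed."""
    text = resources.files("adbm.data").joinpath("default_scenario.json").read_text()
    raw = json.loads(text)
    tp = raw["true_params"]
    params = ADBMParams(a=10.0 ** tp["log10_a"], ai=tp["ai"], aj=tp["aj"], b=tp["b"])
    return SyntheticScenario(
        S=raw["S"],
        log10_mass_bounds=tuple(raw["log10_mass_bounds"]),
        true_params=params,
        removal_prob=raw["removal_prob"],
        seed=raw["seed"] if seed is None else seed,
    )


def generate_community(
    S: int, log10_mass_bounds: tuple[float, float], seed: int
) -> Community:
    """Draw S log-uniform body masses and label them s001..sNNN."""
    rng = np.random.default_rng(seed)
    lo, hi = log10_mass_bounds
    masses = 10.0 ** rng.uniform(lo, hi, size=S)
    width = max(3, len(str(S)))
    labels = [f"s{k + 1:0{width}d}" for k in range(S)]
    return Community.from_data(labels, masses)


def generate_truth(community: Community, true_params: ADBMParams) -> PredationMatrix:
    """Ground-truth web: the deterministic ADBM prediction under known parameters."""
    return predict_web(community, true_params)


def degrade_web(web: PredationMatrix, q: float, seed: int) -> PredationMatrix:
    """Delete each link independently with probability q (under-sampling)."""
    if not (0 <= q <= 1):
        raise ValueError("q must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.uniform(size=web.links.shape) >= q
    return PredationMatrix(web.community, web.links * keep)


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of one under-sampling recovery experiment."""

    scenario: SyntheticScenario
    truth_connectance: float
    degraded_connectance: float
    chosen_tol: float
    posterior_mean_connectance: float
    mean_tss_vs_truth: float
    posterior_summary: pd.DataFrame = field(compare=False)
    param_covered: dict[str, bool] = field(compare=False)
    attempts_used: int = 0


def recovery_experiment(
    scenario: SyntheticScenario,
    prior: PriorSpec | None = None,
    n_accept: int = 200,
    tol_grid: "np.ndarray | list[float] | None" = None,
    n_reference: int = 2000,
    level: float = 0.95,
    max_attempts: int = 1_000_000,
) -> RecoveryReport:
    """Fit the ADBM by ABC to an under-sampled web and score recovery of the truth.

    The ground-truth web is generated from the scenario's parameters, links
    are deleted at rate ``removal_prob``, a distance threshold is selected on
    the degraded web, ABC is run against the degraded web, and the accepted
    webs are scored (TSS) against the *undegraded* truth. All randomness
    derives from ``scenario.seed``.
    """
    if prior is None:
        prior = PriorSpec(log10_a_bounds=(-10.0, 5.0))
    if tol_grid is None:
        tol_grid = np.round(np.arange(0.1, 1.55, 0.1), 10)

    ss = np.random.SeedSequence(scenario.seed)
    s_comm, s_degrade, s_thresh, s_abc = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))

    community = generate_community(scenario.S, scenario.log10_mass_bounds, s_comm)
    truth = generate_truth(community, scenario.true_params)
    degraded = degrade_web(truth, scenario.removal_prob, s_degrade)

    scan = select_threshold(
        degraded, community, prior, tol_grid, seed=s_thresh, n_reference=n_reference
    )
    post = rejection_abc(
        degraded,
        community,
        prior,
        ABCConfig(tol=scan.tol, n_accept=n_accept, seed=s_abc, max_attempts=max_attempts),
    )
    pp = posterior_predictive(post, community)
    tss_vs_truth = [
        true_skill_statistic(confusion_counts(truth, w)) for w in pp.webs
    ]
    summary = summarize_posterior(post, level=level)

    truths = {
        "log10_a": scenario.true_params.log10_a,
        "ai": scenario.true_params.ai,
        "aj": scenario.true_params.aj,
        "log10_b": scenario.true_params.log10_b,
    }
    covered = {
        name: bool(summary.loc[name, "lower"] <= v <= summary.loc[name, "upper"])
        for name, v in truths.items()
    }
    return RecoveryReport(
        scenario=scenario,
        truth_connectance=connectance(truth),
        degraded_connectance=connectance(degraded),
        chosen_tol=scan.tol,
        posterior_mean_connectance=float(summary.loc["connectance", "mean"]),
        mean_tss_vs_truth=float(np.mean(tss_vs_truth)),
        posterior_summary=summary,
        param_covered=covered,
        attempts_used=post.attempts_used,
    )
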