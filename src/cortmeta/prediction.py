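"""Posterior predictive machinery: the next study, hypothetical trials, and
a leave-one-out predictive p-value for trial consistency.

The predictive distribution of the treatment effect in a new study draws
``delta_new ~ N(d, tau^2)`` for every retained posterior draw, so it widens
the pooled-effect posterior by the between-trial heterogeneity.  Simulating
an entire replicate *study* additionally needs a replicate baseline, which
only exists under the exchangeable-baseline model (``mu_new ~ N(m,
sigma_mu^2)``); binomial sampling noise at the chosen arm sizes then yields
a simulated observed odds ratio.

The leave-one-out predictive p-value asks whether an index trial is
consistent with the others: the model is fitted without it, replicate
studies of the same size are drawn, and the p-value is the fraction of
replicate observed (continuity-corrected) odds ratios at least as extreme
as the index trial's, in the tail pointing away from the pooled effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .hierarchical_model import (
    MCMCConfig,
    PosteriorChains,
    PosteriorSummary,
    fit_or_model,
    gelman_rubin,
)
from .trial_data import DataError, MetaDataset, observed_log_or

__all__ = [
    "PredictiveResult",
    "predictive_new_study",
    "hypothetical_trial",
    "predictive_pvalue_loo",
]

logger = logging.getLogger(__name__)

_NEW_STUDY_SALT = 0x5EED01
_REPLICATE_SALT = 0x5EED02


@dataclass
class PredictiveResult:
    """Output of a predictive simulation.

    ``replicate_draws`` holds simulated observed odds ratios when a trial
    size was specified; ``pvalue`` (with Monte-Carlo standard error
    ``mc_se``) and the tail ``direction`` are present for the leave-one-out
    consistency check.
    """

    new_effect_summary: PosteriorSummary
    replicate_draws: np.ndarray | None = None
    pvalue: float | None = None
    direction: str | None = None
    mc_se: float | None = None
    n_reps: int | None = None
    seed: int | None = None
    observed_or: float | None = None
    chains: PosteriorChains | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        doc = {
            "new_effect": self.new_effect_summary.as_dict(),
            "pvalue": self.pvalue,
            "direction": self.direction,
            "mc_se": self.mc_se,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "observed_or": self.observed_or,
        }
        if self.replicate_draws is not None:
            lo, me, hi = np.quantile(self.replicate_draws, [0.025, 0.5, 0.975])
            doc["replicate_or"] = {"median": float(me), "cri_low": float(lo), "cri_high": float(hi)}
        doc.update(self.extras)
        return doc


def _summary(per_chain: np.ndarray, threshold: float) -> PosteriorSummary:
    pooled = per_chain.reshape(-1)
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    return PosteriorSummary(
        median=float(np.median(pooled)),
        cri_low=float(lo),
        cri_high=float(hi),
        prob_ge_threshold=float(np.mean(pooled >= threshold)),
        rhat=gelman_rubin(per_chain) if per_chain.shape[0] >= 2 else float("nan"),
        threshold=threshold,
    )


def predictive_new_study(chains: PosteriorChains, seed: int | None = None) -> PosteriorSummary:
    """Predictive distribution of the effect in the next study.

    For each retained draw, ``delta_new ~ N(d, tau^2)``; on the odds-ratio
    metric the summary is of ``exp(delta_new)`` with exceedance threshold 1,
    on the risk-difference metric of ``delta_new`` itself with threshold 0.
    """
    d = chains.draws["d"]
    tau = chains.draws["tau"]
    entropy = chains.config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([entropy, _NEW_STUDY_SALT]))
    delta_new = d + tau * rng.standard_normal(d.shape)
    if chains.metric == "or":
        return _summary(np.exp(delta_new), threshold=1.0)
    return _summary(delta_new, threshold=0.0)


def _require(chains: PosteriorChains, names: tuple[str, ...], context: str) -> None:
    missing = [n for n in names if n not in chains.draws]
    if missing:
        raise DataError(
            f"{context} needs a hierarchical-baseline fit (missing draws: {missing})"
        )


def _simulate_replicates(
    chains: PosteriorChains,
    n_steroid: int,
    n_control: int,
    n_reps: int,
    rng: np.random.Generator,
    correction: float = 0.5,
) -> np.ndarray:
    """Simulated observed log-ORs of replicate studies drawn from the posterior."""
    _require(chains, ("m", "sigma_mu"), "replicate-study simulation")
    d = chains.pooled("d")
    tau = chains.pooled("tau")
    m = chains.pooled("m")
    sig = chains.pooled("sigma_mu")
    idx = rng.integers(0, d.size, size=n_reps)
    delta_new = d[idx] + tau[idx] * rng.standard_normal(n_reps)
    mu_new = m[idx] + sig[idx] * rng.standard_normal(n_reps)
    p_c = expit(mu_new)
    p_t = expit(mu_new + delta_new)
    r_t = rng.binomial(n_steroid, p_t).astype(float)
    r_c = rng.binomial(n_control, p_c).astype(float)
    cells = np.stack([r_t, n_steroid - r_t, r_c, n_control - r_c])
    zero = (cells == 0).any(axis=0)
    cells = np.where(zero[None, :], cells + correction, cells)
    return np.log(cells[0] / cells[1]) - np.log(cells[2] / cells[3])


def hypothetical_trial(
    chains: PosteriorChains,
    n_total: int,
    n_reps: int = 20_000,
    seed: int | None = None,
) -> PredictiveResult:
    """Predicted observed OR of a hypothesized future trial of ``n_total`` patients.

    Patients split evenly between arms; each replicate draws the pooled
    effect, heterogeneity and a replicate baseline from the posterior, then
    binomial counts, and records the continuity-corrected observed OR.
    """
    if n_total < 4:
        raise DataError("n_total must be >= 4")
    entropy = chains.config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([entropy, _REPLICATE_SALT, n_total]))
    n_arm = n_total // 2
    rep_lor = _simulate_replicates(chains, n_arm, n_total - n_arm, n_reps, rng)
    return PredictiveResult(
        new_effect_summary=predictive_new_study(chains, seed=seed),
        replicate_draws=np.exp(rep_lor),
        n_reps=n_reps,
        seed=entropy,
        chains=chains,
        extras={"n_total": n_total},
    )


def predictive_pvalue_loo(
    data: MetaDataset,
    target_trial: str,
    config: MCMCConfig | None = None,
    n_reps: int = 20_000,
) -> PredictiveResult:
    """Leave-one-out Bayesian predictive p-value for one trial's consistency.

    Fits the exchangeable-baseline model on the other trials, simulates
    ``n_reps`` replicate studies with the target's arm sizes, and reports
    the one-sided tail probability that a replicate observed OR is at least
    as extreme as the target's, the tail chosen away from the pooled
    effect.  Small values flag the target as inconsistent with the rest.
    """
    config = config or MCMCConfig()
    if target_trial not in data.trial_ids:
        raise DataError(f"target trial {target_trial!r} not in dataset {data.trial_ids}")
    rest = data.exclude(target_trial)
    if len(rest) < 3:
        raise DataError("predictive p-value needs >= 3 remaining trials")
    target = next(t for t in data.trials if t.trial_id == target_trial)

    chains = fit_or_model(rest, config, baseline="hierarchical")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _REPLICATE_SALT]))
    rep_lor = _simulate_replicates(
        chains, target.steroid.total, target.control.total, n_reps, rng
    )
    lor_obs, _ = observed_log_or(target.steroid, target.control)
    pooled_med = float(np.median(chains.pooled("d")))
    if lor_obs >= pooled_med:
        direction = "upper"
        p = float(np.mean(rep_lor >= lor_obs))
    else:
        direction = "lower"
        p = float(np.mean(rep_lor <= lor_obs))
    mc_se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_reps))
    logger.info(
        "predictive p-value for %s: %.4f (mc se %.4f, %s tail, observed OR %.3f)",
        target_trial,
        p,
        mc_se,
        direction,
        np.exp(lor_obs),
    )
    return PredictiveResult(
        new_effect_summary=predictive_new_study(chains),
        replicate_draws=np.exp(rep_lor),
        pvalue=p,
        direction=direction,
        mc_se=mc_se,
        n_reps=n_reps,
        seed=config.seed,
        observed_or=float(np.exp(lor_obs)),
        chains=chains,
    )
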