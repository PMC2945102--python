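"""Bayesian meta-regression of the trial effect on a covariate.

Two covariate kinds are supported:

* a *fixed* trial covariate (e.g. mean patient age), centred at the mean of
  the included trials, with the trial effect drawn as
  ``delta_i ~ N(d + beta * (x_i - x_bar), tau^2)``;
* the *latent control-arm baseline*: the baselines are exchangeable,
  ``mu_i ~ N(m, sigma_mu^2)``, and the covariate entering the effect model
  is the latent ``mu_i`` itself (log-odds scale, odds-ratio metric) or its
  inverse-logit (control-arm risk, risk-difference metric), centred at the
  population value.  Because the covariate is the latent quantity rather
  than the noisy observed control rate, regression to the mean and
  regression-dilution bias are handled inside the model rather than by a
  post-hoc correction.

On the risk-difference metric the fitted regression line crosses zero
effect at a covariate value ``x* = center - rd / beta``;
:func:`crossover_point` summarises the posterior of that ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hierarchical_model import (
    MCMCConfig,
    PosteriorChains,
    PosteriorSummary,
    _run_sampler,
    gelman_rubin,
    summarize,
)
from .trial_data import DataError, MetaDataset

__all__ = [
    "MetaRegressionResult",
    "CrossoverUndefinedError",
    "fit_metareg_fixed",
    "fit_metareg_baseline",
    "crossover_point",
    "regression_line_table",
]

logger = logging.getLogger(__name__)


class CrossoverUndefinedError(ValueError):
    """The slope posterior is too concentrated at zero for a crossover ratio."""


@dataclass
class MetaRegressionResult:
    """Posterior summaries of a meta-regression fit.

    ``intercept_summary`` is the pooled effect at the covariate centre
    (reported as an odds ratio on the OR metric); ``slope_summary`` carries
    ``prob_ge_threshold`` with threshold 0, the exceedance probability
    P(beta >= 0).
    """

    intercept_summary: PosteriorSummary
    slope_summary: PosteriorSummary
    tau_summary: PosteriorSummary
    covariate_center: float
    chains: PosteriorChains
    metric: str
    covariate: str
    n_included: int
    dropped_trials: list[str]

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "covariate": self.covariate,
            "n_included": self.n_included,
            "dropped_trials": self.dropped_trials,
            "covariate_center": self.covariate_center,
            "intercept": self.intercept_summary.as_dict(),
            "beta": self.slope_summary.as_dict(),
            "tau": self.tau_summary.as_dict(),
        }


def _result_from_chains(
    chains: PosteriorChains, metric: str, covariate: str, dropped: list[str]
) -> MetaRegressionResult:
    effect_name = "or" if metric == "or" else "rd"
    effect_thr = 1.0 if metric == "or" else 0.0
    return MetaRegressionResult(
        intercept_summary=summarize(chains, effect_name, effect_thr),
        slope_summary=summarize(chains, "beta", 0.0),
        tau_summary=summarize(chains, "tau", 0.0),
        covariate_center=float(np.median(chains.center_draws)),
        chains=chains,
        metric=metric,
        covariate=covariate,
        n_included=len(chains.trial_ids),
        dropped_trials=dropped,
    )


def fit_metareg_fixed(
    data: MetaDataset,
    covariate: str,
    config: MCMCConfig | None = None,
    metric: str = "or",
) -> MetaRegressionResult:
    """Meta-regression on a fixed, observed trial covariate.

    Trials missing the covariate are dropped (with a logged notice); at
    least three usable trials are required.  For ``covariate="age"`` the
    value is the unweighted mean of the two arm mean ages.
    """
    config = config or MCMCConfig()
    values = data.covariate_values(covariate)
    usable = [i for i, v in enumerate(values) if v is not None]
    dropped = [tid for i, tid in enumerate(data.trial_ids) if i not in usable]
    if len(usable) < 3:
        raise DataError(
            f"meta-regression needs >= 3 trials with covariate {covariate!r}; "
            f"only {len(usable)} of {len(data)} usable"
        )
    if dropped:
        logger.info("meta-regression on %r drops trials missing it: %s", covariate, dropped)
    sub = data.subset([data.trial_ids[i] for i in usable])
    x = np.array([values[i] for i in usable], dtype=float)
    if np.ptp(x) == 0:
        logger.warning(
            "covariate %r is constant across trials; the slope posterior is its prior", covariate
        )
    chains = _run_sampler(
        sub, config, metric=metric, baseline="hierarchical", covariate="fixed", x=x
    )
    return _result_from_chains(chains, metric, covariate, dropped)


def fit_metareg_baseline(
    data: MetaDataset, config: MCMCConfig | None = None, metric: str = "or"
) -> MetaRegressionResult:
    """Meta-regression on the latent control-arm baseline.

    The covariate is the trial's true baseline: its log-odds on the OR
    metric, its risk (inverse-logit) on the RD metric, centred at the
    corresponding transform of the population mean ``m``.
    """
    config = config or MCMCConfig()
    if len(data) < 3:
        raise DataError(f"baseline meta-regression needs >= 3 trials, got {len(data)}")
    chains = _run_sampler(
        data, config, metric=metric, baseline="hierarchical", covariate="baseline"
    )
    name = "baseline log-odds" if metric == "or" else "baseline risk"
    return _result_from_chains(chains, metric, name, dropped=[])


def crossover_point(
    result: MetaRegressionResult, eps: float = 1e-3
) -> tuple[PosteriorSummary, float]:
    """Posterior of the covariate value where the regression line crosses RD = 0.

    Per draw, ``x* = center - rd / beta``; draws with ``|beta| <= eps`` are
    excluded from the ratio and the retained fraction is returned alongside
    the summary.  If more than half the draws are excluded the crossover is
    declared undefined.
    """
    if result.metric != "rd":
        raise DataError("crossover_point requires a risk-difference-metric meta-regression")
    chains = result.chains
    rd = chains.draws["d"]
    beta = chains.draws["beta"]
    center = chains.center_draws
    keep = np.abs(beta) > eps
    retained = float(keep.mean())
    if retained < 0.5:
        raise CrossoverUndefinedError(
            f"crossover undefined: only {retained:.1%} of slope draws exceed |beta| > {eps}"
        )
    xstar = center - rd / beta
    # per-chain truncation to a common length so R-hat is computable
    min_len = int(keep.sum(axis=1).min())
    per_chain = np.stack([xstar[c][keep[c]][:min_len] for c in range(xstar.shape[0])])
    pooled = per_chain.reshape(-1)
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    plug_in = result.covariate_center - np.median(rd) / np.median(beta)
    logger.info(
        "crossover: ratio-posterior median %.4f (plug-in ratio of medians %.4f), "
        "retained fraction %.3f",
        float(np.median(pooled)),
        float(plug_in),
        retained,
    )
    summary = PosteriorSummary(
        median=float(np.median(pooled)),
        cri_low=float(lo),
        cri_high=float(hi),
        prob_ge_threshold=float(np.mean(pooled >= 0.0)),
        rhat=gelman_rubin(per_chain) if min_len >= 10 else float("nan"),
        threshold=0.0,
    )
    return summary, retained


def regression_line_table(result: MetaRegressionResult, grid: np.ndarray) -> dict:
    """Predicted effect (median and 95% CrI) over a covariate grid, for plotting."""
    chains = result.chains
    d = chains.draws["d"].reshape(-1)
    beta = chains.draws["beta"].reshape(-1)
    center = chains.center_draws.reshape(-1)
    rows = []
    for x in np.asarray(grid, dtype=float):
        eff = d + beta * (x - center)
        if result.metric == "or":
            eff = np.exp(eff)
        lo, hi = np.quantile(eff, [0.025, 0.975])
        rows.append(
            {"x": float(x), "median": float(np.median(eff)), "cri_low": float(lo), "cri_high": float(hi)}
        )
    return {"metric": result.metric, "covariate": result.covariate, "line": rows}
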