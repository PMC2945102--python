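"""Bayesian random-effects pooling of 2x2 tables via Metropolis-within-Gibbs.

The model, on the odds-ratio metric, is the binomial-logit hierarchical
model: for trial i with control counts ``r_c[i]/n_c[i]`` and steroid counts
``r_t[i]/n_t[i]``,

.. math::

    r_{c,i} \\sim \\mathrm{Bin}(n_{c,i}, p_{c,i}),\\qquad
    \\mathrm{logit}\\, p_{c,i} = \\mu_i,

    r_{t,i} \\sim \\mathrm{Bin}(n_{t,i}, p_{t,i}),\\qquad
    \\mathrm{logit}\\, p_{t,i} = \\mu_i + \\delta_i,

    \\delta_i \\sim N(d, \\tau^2),

with a vague normal prior on the pooled log odds-ratio ``d``, a uniform
prior on the between-trial SD ``tau``, and either independent vague normal
priors on the baselines ``mu_i`` or (``baseline="hierarchical"``) a normal
population ``mu_i ~ N(m, sigma_mu^2)``.  On the risk-difference metric the
trial effect acts on the probability scale, ``p_t = p_c + rho_i`` with
``rho_i ~ N(d, tau^2)`` and the likelihood truncated to ``0 < p_t < 1``.

The sampler is a blocked Metropolis-within-Gibbs scheme: random-walk
Metropolis updates for each ``mu_i``, each trial effect, ``tau`` (and ``m``,
``sigma_mu`` when hierarchical), with proposal scales adapted during burn-in
toward ~44% acceptance and frozen afterwards; the linear-Gaussian blocks
(``d`` and the meta-regression slope ``beta``) are drawn exactly from their
conjugate conditionals.  All chains advance simultaneously as vectorised
state, seeded from a single master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit, ndtr, ndtri

from .trial_data import MetaDataset

__all__ = [
    "MCMCConfig",
    "PosteriorChains",
    "PosteriorSummary",
    "fit_or_model",
    "fit_rd_model",
    "summarize",
    "gelman_rubin",
    "chains_to_csv",
    "summary_document",
]

logger = logging.getLogger(__name__)

_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings and prior hyper-parameters.

    Defaults follow the analysis protocol: three chains with disparate
    starting values, 10,000 burn-in iterations discarded, 100,000 retained.
    Priors are vague: ``d ~ N(0, 10^2)`` on the log-OR scale, independent
    ``mu_i ~ N(0, 10^2)`` baselines and ``tau ~ U(0, 2)``.  On the
    risk-difference metric the pooled effect prior is ``N(0,1)`` truncated to
    (-1, 1) and ``tau ~ U(0, 1)``.
    """

    n_chains: int = 3
    burn_in: int = 10_000
    iterations: int = 100_000
    seed: int = 20100713
    prior_mu_effect: tuple[float, float] = (0.0, 10.0)
    prior_tau: tuple[float, float] = (0.0, 2.0)
    prior_baseline: tuple[float, float] = (0.0, 10.0)
    prior_rd_effect: tuple[float, float] = (0.0, 1.0)
    prior_tau_rd: tuple[float, float] = (0.0, 1.0)
    prior_beta: tuple[float, float] = (0.0, 10.0)
    prior_baseline_mean: tuple[float, float] = (0.0, 10.0)
    prior_baseline_sd: tuple[float, float] = (0.0, 5.0)
    proposal_sd: float | str = "adaptive"
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.burn_in < 0 or self.iterations < 1:
            raise ValueError("burn_in must be >= 0 and iterations >= 1")
        for name in ("prior_tau", "prior_tau_rd", "prior_baseline_sd"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must satisfy 0 <= lower < upper, got {(lo, hi)}")
        if not isinstance(self.proposal_sd, str) and self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive or 'adaptive'")

    def replace(self, **kwargs) -> "MCMCConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PosteriorSummary:
    """Median, central 95% credible interval, exceedance probability, R-hat."""

    median: float
    cri_low: float
    cri_high: float
    prob_ge_threshold: float
    rhat: float
    threshold: float = np.nan

    def as_dict(self) -> dict:
        return {
            "median": self.median,
            "cri_low": self.cri_low,
            "cri_high": self.cri_high,
            "prob_ge_threshold": self.prob_ge_threshold,
            "threshold": None if np.isnan(self.threshold) else self.threshold,
            "rhat": self.rhat,
        }


@dataclass
class PosteriorChains:
    """Retained MCMC draws, one row per chain, plus fit metadata.

    ``draws`` maps parameter names (``d``, ``tau``, ``beta``/``m``/
    ``sigma_mu`` where present, ``mu[<trial>]``, ``delta[<trial>]``) to
    arrays of shape ``(n_chains, iterations)``.  The derived ``or`` parameter
    (``exp(d)``, odds-ratio metric only) and, for risk-difference fits, the
    ``rd`` alias of ``d`` are available through :meth:`parameter`.
    """

    draws: dict[str, np.ndarray]
    metric: str
    trial_ids: list[str]
    config: MCMCConfig
    acceptance: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    center_draws: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return not any(w.startswith("unconverged") for w in self.warnings)

    def parameter_names(self) -> list[str]:
        names = list(self.draws)
        names.append("or" if self.metric == "or" else "rd")
        return names

    def parameter(self, name: str) -> np.ndarray:
        if name == "or":
            if self.metric != "or":
                raise KeyError("derived parameter 'or' only exists on the odds-ratio metric")
            return np.exp(self.draws["d"])
        if name == "rd" and self.metric == "rd":
            return self.draws["d"]
        try:
            return self.draws[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {self.parameter_names()}"
            ) from None

    def pooled(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)


def gelman_rubin(per_chain_draws) -> float:
    """Gelman-Rubin potential scale reduction factor (between/within form)."""
    draws = np.asarray(per_chain_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("gelman_rubin needs >= 2 chains of equal length")
    n_chains, n = draws.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful R-hat (need length >= 10)")
    chain_means = draws.mean(axis=1)
    within = draws.var(axis=1, ddof=1).mean()
    between_over_n = chain_means.var(ddof=1)
    if within == 0:
        return 1.0 if between_over_n == 0 else np.inf
    var_plus = (n - 1) / n * within + between_over_n
    return float(np.sqrt(var_plus / within))


def summarize(chains: PosteriorChains, parameter: str, threshold: float = 0.0) -> PosteriorSummary:
    """Pooled-chain posterior summary of one scalar parameter.

    ``prob_ge_threshold`` is the fraction of draws at or above ``threshold``
    (for ``parameter="or"`` with ``threshold=1`` this is the exceedance
    probability P(OR >= 1)).
    """
    per_chain = chains.parameter(parameter)
    pooled = per_chain.reshape(-1)
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    return PosteriorSummary(
        median=float(np.median(pooled)),
        cri_low=float(lo),
        cri_high=float(hi),
        prob_ge_threshold=float(np.mean(pooled >= threshold)),
        rhat=gelman_rubin(per_chain),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Sampler engine
# ---------------------------------------------------------------------------


def _binom_logit_loglik(eta, r, n):
    # log L = r*eta - n*log(1 + e^eta), constants dropped
    return r * eta - n * np.logaddexp(0.0, eta)


def _binom_prob_loglik(p, r, n, valid):
    out = np.full(np.shape(p), -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = r * np.log(p) + (n - r) * np.log1p(-p)
    np.copyto(out, ll, where=valid)
    return out


def _normal_logpdf(x, mean, sd):
    return -np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _truncnorm_draw(rng, mean, sd, lo, hi):
    # inverse-CDF sampling, vectorised; mean/sd arrays over chains
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(a, b)
    return mean + sd * ndtri(u)


class _Adaptive:
    """Per-element random-walk scales with Robbins-Monro adaptation."""

    def __init__(self, shape, init_scale, adaptive: bool):
        self.scale = np.full(shape, init_scale, dtype=float)
        self.adaptive = adaptive
        self.accepts = np.zeros(shape, dtype=float)
        self.batch = 0

    def record(self, accepted) -> None:
        self.accepts += accepted

    def adapt(self) -> None:
        if not self.adaptive:
            self.accepts[:] = 0.0
            return
        self.batch += 1
        rate = self.accepts / _ADAPT_WINDOW
        gain = 1.0 / np.sqrt(self.batch)
        self.scale *= np.exp(gain * (rate - _TARGET_ACCEPT))
        np.clip(self.scale, 1e-4, 20.0, out=self.scale)
        self.accepts[:] = 0.0


def _run_sampler(
    data: MetaDataset,
    config: MCMCConfig,
    *,
    metric: str,
    baseline: str,
    covariate: str | None = None,
    x: np.ndarray | None = None,
) -> PosteriorChains:
    """Shared engine behind all model fits.

    ``covariate`` is ``None`` (plain pooling), ``"fixed"`` (``x`` holds the
    trial covariate, centred at its mean) or ``"baseline"`` (the covariate is
    the latent control-arm baseline; requires hierarchical baselines).
    """
    if metric not in ("or", "rd"):
        raise ValueError("metric must be 'or' or 'rd'")
    if baseline not in ("independent", "hierarchical"):
        raise ValueError("baseline must be 'independent' or 'hierarchical'")
    if covariate == "baseline" and baseline != "hierarchical":
        raise ValueError("the latent-baseline covariate requires hierarchical baselines")
    if covariate == "fixed":
        x = np.asarray(x, dtype=float)
        x_center = float(x.mean())
        z_fixed = x - x_center
    else:
        x_center = np.nan
        z_fixed = None

    rt, nt, rc, nc = (np.asarray(v, dtype=float) for v in data.counts())
    K = len(rt)
    C = config.n_chains
    T = config.iterations
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # Priors
    b0, bsd = config.prior_baseline
    pm0, pmsd = config.prior_baseline_mean
    sig_lo, sig_hi = config.prior_baseline_sd
    beta0, betasd = config.prior_beta
    if metric == "or":
        d0, dsd = config.prior_mu_effect
        tau_lo, tau_hi = config.prior_tau
    else:
        d0, dsd = config.prior_rd_effect
        tau_lo, tau_hi = config.prior_tau_rd
    tau_lo_eff = max(tau_lo, 1e-12)

    # --- initial state: disparate across chains --------------------------
    spread = np.linspace(-1.0, 1.0, C)[:, None]  # (C,1)
    pc_obs = (rc + 0.5) / (nc + 1.0)
    pt_obs = (rt + 0.5) / (nt + 1.0)
    mu_obs = logit(pc_obs)
    mu = mu_obs[None, :] + 0.5 * spread
    if metric == "or":
        eff = (logit(pt_obs) - mu_obs)[None, :] + spread
    else:
        pt0 = np.clip(pt_obs, 0.02, 0.98)
        eff = pt0[None, :] - expit(mu)  # keeps p_t = p_c + rho at pt0, inside (0,1)
    frac = (np.arange(C) + 1.0) / (C + 1.0)
    tau = tau_lo_eff + frac * (tau_hi - tau_lo_eff) * 0.9
    d = spread[:, 0] * (1.0 if metric == "or" else 0.1)
    beta = spread[:, 0] * 0.3 if covariate else None
    hier = baseline == "hierarchical"
    m = mu_obs.mean() + 0.5 * spread[:, 0] if hier else None
    sig = np.clip(mu_obs.std() + 0.1, sig_lo + 0.05 * (sig_hi - sig_lo), 0.9 * sig_hi) * (
        0.5 + frac
    )
    sig = np.clip(sig, sig_lo + 1e-3, sig_hi - 1e-3) if hier else None

    adaptive = config.proposal_sd == "adaptive"
    init_scale = 0.5 if adaptive else float(config.proposal_sd)
    st_mu = _Adaptive((C, K), init_scale, adaptive)
    st_eff = _Adaptive((C, K), init_scale if metric == "or" else 0.1, adaptive)
    st_tau = _Adaptive((C,), 0.3 if adaptive else init_scale, adaptive)
    st_shift = _Adaptive((C,), 0.3 if adaptive else init_scale, adaptive)
    st_m = _Adaptive((C,), 0.3 if adaptive else init_scale, adaptive) if hier else None
    st_sig = _Adaptive((C,), 0.3 if adaptive else init_scale, adaptive) if hier else None

    def g_of_mu(mu_arr):
        # covariate transform of the latent baseline
        return mu_arr if metric == "or" else expit(mu_arr)

    def center_of_m(m_arr):
        return m_arr if metric == "or" else expit(m_arr)

    def eff_mean(mu_arr, m_arr, d_arr, beta_arr):
        if covariate is None:
            return d_arr[:, None]
        if covariate == "fixed":
            return d_arr[:, None] + beta_arr[:, None] * z_fixed[None, :]
        return d_arr[:, None] + beta_arr[:, None] * (
            g_of_mu(mu_arr) - center_of_m(m_arr)[:, None]
        )

    def lik_treated(mu_arr, eff_arr):
        if metric == "or":
            return _binom_logit_loglik(mu_arr + eff_arr, rt, nt)
        p_t = expit(mu_arr) + eff_arr
        valid = (p_t > 1e-12) & (p_t < 1 - 1e-12)
        return _binom_prob_loglik(p_t, rt, nt, valid)

    def lik_control(mu_arr):
        return _binom_logit_loglik(mu_arr, rc, nc)

    # storage
    store: dict[str, np.ndarray] = {
        "d": np.empty((C, T)),
        "tau": np.empty((C, T)),
    }
    if covariate:
        store["beta"] = np.empty((C, T))
    if hier:
        store["m"] = np.empty((C, T))
        store["sigma_mu"] = np.empty((C, T))
    store_mu = np.empty((C, T, K))
    store_eff = np.empty((C, T, K))
    center_store = np.empty((C, T)) if covariate else None

    n_total = config.burn_in + T
    for it in range(n_total):
        in_burn = it < config.burn_in

        # --- mu_i block (random-walk Metropolis, all trials at once) ----
        prop = mu + st_mu.scale * rng.standard_normal((C, K))
        cur_mean = eff_mean(mu, m, d, beta)
        cur_lp = (
            lik_control(mu)
            + lik_treated(mu, eff)
            + (
                _normal_logpdf(mu, m[:, None], sig[:, None])
                if hier
                else _normal_logpdf(mu, b0, bsd)
            )
        )
        prop_lp = (
            lik_control(prop)
            + lik_treated(prop, eff)
            + (
                _normal_logpdf(prop, m[:, None], sig[:, None])
                if hier
                else _normal_logpdf(prop, b0, bsd)
            )
        )
        if covariate == "baseline":
            prop_mean = eff_mean(prop, m, d, beta)
            cur_lp = cur_lp + _normal_logpdf(eff, cur_mean, tau[:, None])
            prop_lp = prop_lp + _normal_logpdf(eff, prop_mean, tau[:, None])
        accept = np.log(rng.uniform(size=(C, K))) < prop_lp - cur_lp
        mu = np.where(accept, prop, mu)
        st_mu.record(accept)

        # --- trial-effect block -----------------------------------------
        mean_now = eff_mean(mu, m, d, beta)
        prop = eff + st_eff.scale * rng.standard_normal((C, K))
        cur_lp = lik_treated(mu, eff) + _normal_logpdf(eff, mean_now, tau[:, None])
        prop_lp = lik_treated(mu, prop) + _normal_logpdf(prop, mean_now, tau[:, None])
        accept = np.log(rng.uniform(size=(C, K))) < prop_lp - cur_lp
        eff = np.where(accept, prop, eff)
        st_eff.record(accept)

        # --- d (conjugate Gibbs; truncated normal on the RD metric) -----
        if covariate is None:
            resid = eff
        elif covariate == "fixed":
            resid = eff - beta[:, None] * z_fixed[None, :]
        else:
            zlat = g_of_mu(mu) - center_of_m(m)[:, None]
            resid = eff - beta[:, None] * zlat
        prec = K / tau**2 + 1.0 / dsd**2
        mean_post = (resid.sum(axis=1) / tau**2 + d0 / dsd**2) / prec
        sd_post = 1.0 / np.sqrt(prec)
        if metric == "or":
            d = mean_post + sd_post * rng.standard_normal(C)
        else:
            d = _truncnorm_draw(rng, mean_post, sd_post, -1.0, 1.0)

        # --- beta (conjugate Gibbs) --------------------------------------
        if covariate is not None:
            if covariate == "fixed":
                z = np.broadcast_to(z_fixed[None, :], (C, K))
            else:
                z = g_of_mu(mu) - center_of_m(m)[:, None]
            resid = eff - d[:, None]
            prec = (z**2).sum(axis=1) / tau**2 + 1.0 / betasd**2
            mean_post = ((z * resid).sum(axis=1) / tau**2 + beta0 / betasd**2) / prec
            beta = mean_post + rng.standard_normal(C) / np.sqrt(prec)

        # --- joint translation of (d, all trial effects) ------------------
        # a reparameterisation move: shifting d and every effect by the same
        # amount leaves the N(effect; mean, tau^2) terms unchanged, so the
        # acceptance ratio involves only the treated-arm likelihoods and the
        # prior on d.  Essential for mixing when the tau prior pins
        # heterogeneity near zero and per-effect moves are frozen.
        shift = st_shift.scale * rng.standard_normal(C)
        d_prop = d + shift
        eff_prop = eff + shift[:, None]
        cur_lp = lik_treated(mu, eff).sum(axis=1)
        prop_lp = lik_treated(mu, eff_prop).sum(axis=1)
        cur_lp = cur_lp - 0.5 * ((d - d0) / dsd) ** 2
        prop_lp = prop_lp - 0.5 * ((d_prop - d0) / dsd) ** 2
        if metric == "rd":
            prop_lp = np.where(np.abs(d_prop) < 1.0, prop_lp, -np.inf)
        accept = np.log(rng.uniform(size=C)) < prop_lp - cur_lp
        d = np.where(accept, d_prop, d)
        eff = np.where(accept[:, None], eff_prop, eff)
        st_shift.record(accept)

        # --- tau (random-walk Metropolis, uniform prior) ------------------
        mean_now = eff_mean(mu, m, d, beta)
        prop = tau + st_tau.scale * rng.standard_normal(C)
        ok = (prop > tau_lo_eff) & (prop < tau_hi)
        ssq = ((eff - mean_now) ** 2).sum(axis=1)
        cur_lp = -K * np.log(tau) - 0.5 * ssq / tau**2
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_lp = np.where(ok, -K * np.log(np.where(ok, prop, 1.0)) - 0.5 * ssq / prop**2, -np.inf)
        accept = ok & (np.log(rng.uniform(size=C)) < prop_lp - cur_lp)
        tau = np.where(accept, prop, tau)
        st_tau.record(accept)

        if hier:
            # --- m (random-walk Metropolis) ------------------------------
            prop = m + st_m.scale * rng.standard_normal(C)
            cur_lp = _normal_logpdf(mu, m[:, None], sig[:, None]).sum(axis=1) + _normal_logpdf(
                m, pm0, pmsd
            )
            prop_lp = _normal_logpdf(mu, prop[:, None], sig[:, None]).sum(
                axis=1
            ) + _normal_logpdf(prop, pm0, pmsd)
            if covariate == "baseline":
                cur_lp = cur_lp + _normal_logpdf(
                    eff, eff_mean(mu, m, d, beta), tau[:, None]
                ).sum(axis=1)
                prop_lp = prop_lp + _normal_logpdf(
                    eff, eff_mean(mu, prop, d, beta), tau[:, None]
                ).sum(axis=1)
            accept = np.log(rng.uniform(size=C)) < prop_lp - cur_lp
            m = np.where(accept, prop, m)
            st_m.record(accept)

            # --- sigma_mu (random-walk Metropolis, uniform prior) --------
            prop = sig + st_sig.scale * rng.standard_normal(C)
            ok = (prop > max(sig_lo, 1e-12)) & (prop < sig_hi)
            ssq_mu = ((mu - m[:, None]) ** 2).sum(axis=1)
            cur_lp = -K * np.log(sig) - 0.5 * ssq_mu / sig**2
            with np.errstate(divide="ignore", invalid="ignore"):
                prop_lp = np.where(
                    ok, -K * np.log(np.where(ok, prop, 1.0)) - 0.5 * ssq_mu / prop**2, -np.inf
                )
            accept = ok & (np.log(rng.uniform(size=C)) < prop_lp - cur_lp)
            sig = np.where(accept, prop, sig)
            st_sig.record(accept)

        if in_burn and (it + 1) % _ADAPT_WINDOW == 0:
            for st in (st_mu, st_eff, st_tau, st_shift, st_m, st_sig):
                if st is not None:
                    st.adapt()
        if it == config.burn_in - 1:
            for st in (st_mu, st_eff, st_tau, st_shift, st_m, st_sig):
                if st is not None:
                    st.accepts[:] = 0.0

        if not in_burn:
            t = it - config.burn_in
            store["d"][:, t] = d
            store["tau"][:, t] = tau
            if covariate:
                store["beta"][:, t] = beta
                center_store[:, t] = x_center if covariate == "fixed" else center_of_m(m)
            if hier:
                store["m"][:, t] = m
                store["sigma_mu"][:, t] = sig
            store_mu[:, t, :] = mu
            store_eff[:, t, :] = eff

    draws = dict(store)
    for k_idx, tid in enumerate(data.trial_ids):
        draws[f"mu[{tid}]"] = store_mu[:, :, k_idx]
        draws[f"delta[{tid}]"] = store_eff[:, :, k_idx]

    acceptance = {
        "mu": float(st_mu.accepts.mean() / T),
        "effect": float(st_eff.accepts.mean() / T),
        "tau": float(st_tau.accepts.mean() / T),
        "shift": float(st_shift.accepts.mean() / T),
    }
    if hier:
        acceptance["m"] = float(st_m.accepts.mean() / T)
        acceptance["sigma_mu"] = float(st_sig.accepts.mean() / T)
    logger.info(
        "sampler (%s, %s baselines%s) on %d trials: acceptance %s",
        metric,
        baseline,
        f", {covariate} covariate" if covariate else "",
        K,
        {k: round(v, 3) for k, v in acceptance.items()},
    )

    chains = PosteriorChains(
        draws=draws,
        metric=metric,
        trial_ids=list(data.trial_ids),
        config=config,
        acceptance=acceptance,
        center_draws=center_store,
    )
    for par in ("d", "tau"):
        r = gelman_rubin(chains.draws[par])
        if not r <= config.rhat_threshold:
            msg = f"unconverged: rhat({par}) = {r:.3f} > {config.rhat_threshold}"
            chains.warnings.append(msg)
            logger.warning(msg)
    return chains


def fit_or_model(
    data: MetaDataset, config: MCMCConfig | None = None, baseline: str = "hierarchical"
) -> PosteriorChains:
    """Fit the binomial-logit random-effects model on the odds-ratio metric.

    By default the per-trial baseline log-odds are exchangeable,
    ``mu_i ~ N(m, sigma_mu^2)`` with vague priors on the population mean and
    SD; this is the model whose posterior also supports simulating a
    replicate study baseline.  ``baseline="independent"`` fits the variant
    with independent vague normal priors on each ``mu_i`` instead.
    """
    config = config or MCMCConfig()
    return _run_sampler(data, config, metric="or", baseline=baseline)


def fit_rd_model(
    data: MetaDataset, config: MCMCConfig | None = None, baseline: str = "hierarchical"
) -> PosteriorChains:
    """Fit the random-effects model on the (absolute) risk-difference metric.

    Trial effects act on the probability scale, ``p_t = p_c + rho_i``;
    proposals leaving (0, 1) are rejected so the posterior is correctly
    truncated to the feasible region.
    """
    config = config or MCMCConfig()
    return _run_sampler(data, config, metric="rd", baseline=baseline)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def chains_to_csv(chains: PosteriorChains, directory) -> list[Path]:
    """Write retained draws to CSV, one file per chain, one column per parameter."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = list(chains.draws)
    paths = []
    for c in range(chains.config.n_chains):
        path = directory / f"chain_{c + 1}.csv"
        mat = np.column_stack([chains.draws[n][c] for n in names])
        header = ",".join(names)
        np.savetxt(path, mat, delimiter=",", header=header, comments="")
        paths.append(path)
    return paths


def summary_document(chains: PosteriorChains, thresholds: dict[str, float] | None = None) -> dict:
    """JSON-ready summary: parameter -> {median, cri, prob, rhat}."""
    thresholds = thresholds or {}
    default_thr = 1.0 if chains.metric == "or" else 0.0
    doc = {
        "metric": chains.metric,
        "trials": chains.trial_ids,
        "seed": chains.config.seed,
        "converged": chains.converged,
        "warnings": list(chains.warnings),
        "parameters": {},
    }
    headline = ["or" if chains.metric == "or" else "rd", "tau"]
    for extra in ("beta", "m", "sigma_mu"):
        if extra in chains.draws:
            headline.append(extra)
    for name in headline:
        thr = thresholds.get(name, default_thr if name in ("or", "rd") else 0.0)
        doc["parameters"][name] = summarize(chains, name, thr).as_dict()
    return doc


def write_summary_json(chains: PosteriorChains, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary_document(chains), fh, indent=2)
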