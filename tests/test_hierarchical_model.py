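"""Sampler correctness: summaries, convergence diagnostics, limits, symmetries."""

import numpy as np
import pytest

from cortmeta.hierarchical_model import (
    MCMCConfig,
    chains_to_csv,
    fit_or_model,
    fit_rd_model,
    gelman_rubin,
    summarize,
    summary_document,
)
from cortmeta.trial_data import ArmCount, MetaDataset, TrialArms, observed_log_or


def _single_trial_dataset(rt, nt, rc, nc):
    return MetaDataset(
        "mortality", "synthetic", [TrialArms("t1", ArmCount(rt, nt), ArmCount(rc, nc))]
    )


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        # the classical PSRF of identical chains is sqrt((n-1)/n), i.e. 1 - O(1/n)
        x = np.linspace(-2, 2, 500)
        assert gelman_rubin(np.stack([x, x])) == pytest.approx(1.0, abs=2e-3)

    def test_disparate_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        r = gelman_rubin(chains)
        # brute-force variance-ratio oracle
        n = 1000
        within = chains.var(axis=1, ddof=1).mean()
        b_over_n = chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * within + b_over_n) / within)
        assert r == pytest.approx(expected, rel=1e-12)
        assert r > 1.1

    def test_converged_fit_below_threshold(self, low9, medium_config):
        chains = fit_or_model(low9, medium_config)
        assert gelman_rubin(chains.draws["d"]) < 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestSummarize:
    def test_degenerate_chains(self):
        from cortmeta.hierarchical_model import PosteriorChains

        chains = PosteriorChains(
            draws={"d": np.ones((2, 100)), "tau": np.zeros((2, 100))},
            metric="rd",
            trial_ids=["t1"],
            config=MCMCConfig(burn_in=0, iterations=100),
        )
        s = summarize(chains, "d", 1.0)
        assert s.median == 1.0 and s.prob_ge_threshold == 1.0

    def test_standard_normal_quantiles(self):
        from cortmeta.hierarchical_model import PosteriorChains

        rng = np.random.default_rng(1)
        draws = rng.standard_normal((2, 50_000))
        chains = PosteriorChains(
            draws={"d": draws, "tau": np.zeros_like(draws)},
            metric="rd",
            trial_ids=["t1"],
            config=MCMCConfig(burn_in=0, iterations=50_000),
        )
        s = summarize(chains, "d", 0.0)
        assert s.median == pytest.approx(0.0, abs=0.02)
        assert s.prob_ge_threshold == pytest.approx(0.5, abs=0.01)
        assert s.cri_low == pytest.approx(-1.96, abs=0.05)
        assert s.cri_high == pytest.approx(1.96, abs=0.05)

    def test_unknown_parameter(self, low9, fast_config):
        chains = fit_or_model(low9, fast_config)
        with pytest.raises(KeyError):
            summarize(chains, "nope", 0.0)


class TestORModel:
    def test_identical_arms_or_near_one(self, fast_config):
        data = _single_trial_dataset(50, 100, 50, 100)
        cfg = fast_config.replace(prior_tau=(0.0, 0.001), iterations=6000)
        s = summarize(fit_or_model(data, cfg), "or", 1.0)
        assert s.median == pytest.approx(1.0, abs=0.1)

    def test_rd_identical_arms_near_zero(self, fast_config):
        data = _single_trial_dataset(50, 100, 50, 100)
        cfg = fast_config.replace(prior_tau_rd=(0.0, 0.001), iterations=6000)
        s = summarize(fit_rd_model(data, cfg), "rd", 0.0)
        assert s.median == pytest.approx(0.0, abs=0.03)

    def test_fixed_effect_limit_matches_inverse_variance_pool(self, low9, medium_config):
        """With tau pinned near zero the posterior mean effect must collapse to
        the classical inverse-variance-weighted pooled log-OR."""
        pairs = [observed_log_or(t.steroid, t.control) for t in low9.trials]
        w = np.array([1 / se**2 for _, se in pairs])
        ivw = float(np.sum(w * np.array([lor for lor, _ in pairs])) / w.sum())
        cfg = medium_config.replace(prior_tau=(0.0, 1e-4))
        chains = fit_or_model(low9, cfg, baseline="independent")
        assert float(np.median(chains.pooled("d"))) == pytest.approx(ivw, abs=0.03)

    def test_label_symmetry(self, low8, medium_config):
        fwd = summarize(fit_or_model(low8, medium_config), "or", 1.0)
        rev = summarize(fit_or_model(low8.swap_arms(), medium_config), "or", 1.0)
        assert np.log(fwd.median) == pytest.approx(-np.log(rev.median), abs=0.05)

    def test_order_invariance(self, low8, medium_config):
        perm = list(reversed(low8.trial_ids))
        a = summarize(fit_or_model(low8, medium_config), "or", 1.0)
        b = summarize(fit_or_model(low8.subset(perm), medium_config), "or", 1.0)
        assert a.median == pytest.approx(b.median, abs=0.05)
        assert a.prob_ge_threshold == pytest.approx(b.prob_ge_threshold, abs=0.03)

    def test_seeded_runs_are_identical(self, low8, fast_config):
        a = fit_or_model(low8, fast_config)
        b = fit_or_model(low8, fast_config)
        assert np.array_equal(a.draws["d"], b.draws["d"])
        assert np.array_equal(a.draws["tau"], b.draws["tau"])

    def test_short_chains_flag_unconverged(self, low9):
        cfg = MCMCConfig(burn_in=0, iterations=60, seed=0)
        chains = fit_or_model(low9, cfg)
        assert not chains.converged
        assert any("unconverged" in w for w in chains.warnings)

    def test_tau_draws_respect_prior_support(self, low9, fast_config):
        chains = fit_or_model(low9, fast_config)
        tau = chains.pooled("tau")
        lo, hi = fast_config.prior_tau
        assert np.all((tau > lo) & (tau < hi))

    def test_rd_draws_keep_probabilities_valid(self, low9, fast_config):
        chains = fit_rd_model(low9, fast_config)
        from scipy.special import expit

        for tid in chains.trial_ids:
            p_t = expit(chains.draws[f"mu[{tid}]"]) + chains.draws[f"delta[{tid}]"]
            assert np.all((p_t > 0) & (p_t < 1))
        rd = chains.pooled("rd")
        assert np.all((rd > -1) & (rd < 1))


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=0)
        with pytest.raises(ValueError):
            MCMCConfig(prior_tau=(2.0, 1.0))
        with pytest.raises(ValueError):
            MCMCConfig(proposal_sd=-1.0)


class TestExports:
    def test_chain_csv_and_summary_json(self, low8, fast_config, tmp_path):
        chains = fit_or_model(low8, fast_config)
        paths = chains_to_csv(chains, tmp_path)
        assert len(paths) == fast_config.n_chains
        header = paths[0].read_text().splitlines()[0]
        assert "d" in header.split(",") and "tau" in header.split(",")
        doc = summary_document(chains)
        assert set(doc["parameters"]) >= {"or", "tau"}
        assert doc["parameters"]["or"]["median"] > 0
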