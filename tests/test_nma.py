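"""Model construction, MCMC behavior, summaries, and residual deviance."""

from dataclasses import replace

import numpy as np
import pytest

from dosenma.data_model import expand_trials
from dosenma.nma import (
    MCMCConfig,
    NMAPosterior,
    binomial_deviance_points,
    build_model,
    consistency_contrast,
    fit,
    gelman_rubin,
    normal_deviance_points,
    residual_deviance,
    summarize,
)
from dosenma.synthetic import default_published_config, simulate_network, with_seed

from conftest import bin_arm, cont_arm


class TestBuildModel:
    def test_published_geometry_binary_counts(self, binary_bundle):
        spec = build_model(list(binary_bundle.arms), "binary")
        assert spec.n_datapoints == 50  # one point per arm
        assert spec.n_baselines == 24
        assert spec.n_basic_parameters == 2

    def test_single_trial_model(self):
        arms = [bin_arm("S1", "PBO", 100, 10), bin_arm("S1", "C200QD", 100, 12)]
        spec = build_model(arms, "binary")
        assert spec.n_trials == 1
        assert spec.n_basic_parameters == 1

    def test_reference_must_be_present(self):
        arms = [bin_arm("S1", "A", 100, 10), bin_arm("S1", "B", 100, 12)]
        with pytest.raises(ValueError):
            build_model(arms, "binary", reference="PBO")

    def test_continuous_counts_contrasts(self, continuous_bundle):
        spec = build_model(list(continuous_bundle.arms), "continuous")
        # 24 trials, 2 of them three-arm: arms minus trials contrasts
        assert spec.n_datapoints == 50 - 24

    def test_table1_geometry_has_50_arms(self, table1):
        assert sum(len(ts) for _, ts in expand_trials(table1)) == 50


class TestFit:
    def test_symmetric_binary_trial_centers_at_zero(self):
        arms = [bin_arm("S1", "PBO", 100, 10), bin_arm("S1", "C200QD", 100, 10)]
        spec = build_model(arms, "binary")
        post = fit(spec, MCMCConfig(n_chains=3, n_iter=20000, n_burnin=4000,
                                    base_seed=5))
        med, _, _ = post.contrast_summary("C200QD", "PBO")
        assert abs(med) < 0.05

    def test_same_seed_reproduces_draws(self, continuous_bundle):
        spec = build_model(list(continuous_bundle.arms), "continuous")
        cfg = MCMCConfig(n_chains=2, n_iter=1200, n_burnin=400, base_seed=21)
        a, b = fit(spec, cfg), fit(spec, cfg)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.tau, b.tau)

    def test_different_seed_changes_draws(self, continuous_bundle):
        spec = build_model(list(continuous_bundle.arms), "continuous")
        a = fit(spec, MCMCConfig(n_chains=2, n_iter=1200, n_burnin=400,
                                 base_seed=21))
        b = fit(spec, MCMCConfig(n_chains=2, n_iter=1200, n_burnin=400,
                                 base_seed=22))
        assert not np.array_equal(a.d, b.d)

    def test_binary_same_seed_reproduces(self, binary_bundle):
        spec = build_model(list(binary_bundle.arms), "binary")
        cfg = MCMCConfig(n_chains=2, n_iter=800, n_burnin=300, base_seed=13)
        a, b = fit(spec, cfg), fit(spec, cfg)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.delta, b.delta)

    def test_indirect_only_network_still_identifies_contrast(self):
        # remove all direct QD-BID trials: the QD-vs-BID posterior exists and
        # is the draw-wise difference of basic parameters by construction
        cfg = with_seed(default_published_config("continuous"), 31)
        cfg = replace(cfg, designs=((("C100BID", "PBO"), 6),
                                    (("C200QD", "PBO"), 10)))
        bundle = simulate_network(cfg, "continuous")
        spec = build_model(list(bundle.arms), "continuous")
        post = fit(spec, MCMCConfig(n_chains=2, n_iter=3000, n_burnin=800,
                                    base_seed=3))
        diff = post.contrast_draws("C200QD", "C100BID")
        manual = (post.contrast_draws("C200QD", "PBO")
                  - post.contrast_draws("C100BID", "PBO"))
        assert np.allclose(diff, manual)


class TestSummaries:
    def test_league_table_skew_symmetric(self, continuous_bundle, quick_mcmc):
        spec = build_model(list(continuous_bundle.arms), "continuous")
        post = fit(spec, quick_mcmc)
        league = summarize(post)
        ab = league[(league.x == "C200QD") & (league.y == "PBO")].iloc[0]
        ba = league[(league.x == "PBO") & (league.y == "C200QD")].iloc[0]
        assert ab["median"] == pytest.approx(-ba["median"])
        assert ab["lower"] == pytest.approx(-ba["upper"])

    def test_constant_shift_summarizes_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2, 500, 1))
        d = np.concatenate([base, base + 0.04], axis=2)
        post = NMAPosterior(treatments=("PBO", "A", "B"), reference="PBO",
                            scale="smd", d=d, tau=np.ones((2, 500)) * 0.1,
                            trial_ids=("S1",))
        med, lo, hi = post.contrast_summary("B", "A")
        assert (med, lo, hi) == pytest.approx((0.04, 0.04, 0.04))

    def test_self_contrast_is_degenerate_zero(self, continuous_bundle,
                                              quick_mcmc):
        spec = build_model(list(continuous_bundle.arms), "continuous")
        post = fit(spec, quick_mcmc)
        draws = post.contrast_draws("C200QD", "C200QD")
        assert np.all(draws == 0.0)

    @pytest.mark.parametrize("dx,dy,scale,expected", [
        (-0.38, -0.42, "smd", 0.04),
        (-0.40, -0.43, "smd", 0.03),
        (0.5, 0.5, "smd", 0.0),
        (2.0, 0.5, "or", 4.0),
    ])
    def test_consistency_contrast(self, dx, dy, scale, expected):
        assert consistency_contrast(dx, dy, scale) == pytest.approx(expected)


class TestGelmanRubin:
    def _posterior_from(self, chains):
        d = np.asarray(chains)[:, :, None]
        return NMAPosterior(treatments=("PBO", "A"), reference="PBO",
                            scale="smd", d=d,
                            tau=np.full(d.shape[:2], 0.1), trial_ids=("S1",))

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(1)
        post = self._posterior_from(rng.normal(size=(3, 4000)))
        assert gelman_rubin(post)["d_A"] < 1.01

    def test_offset_chain_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 1000))
        chains[0] += 10.0
        assert gelman_rubin(self._posterior_from(chains))["d_A"] > 1.1

    def test_single_chain_rejected(self):
        post = self._posterior_from(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(post)


class TestResidualDeviance:
    def test_saturated_normal_fit_is_zero(self):
        y = np.array([0.2, -0.1, 0.4])
        v = np.array([0.1, 0.2, 0.05])
        theta = np.tile(y, (50, 1))
        assert normal_deviance_points(y, v, theta).sum() == pytest.approx(0.0)

    def test_binomial_zero_events_finite(self):
        contrib = binomial_deviance_points(
            np.array([0, 5]), np.array([10, 10]),
            np.full((20, 2), 0.3))
        assert np.all(np.isfinite(contrib)) and np.all(contrib >= 0)

    def test_contributions_sum_to_total(self, binary_bundle, quick_mcmc):
        spec = build_model(list(binary_bundle.arms), "binary")
        post = fit(spec, quick_mcmc)
        rep = residual_deviance(post, spec)
        assert sum(rep.contributions.values()) == pytest.approx(rep.D_res)
        assert len(rep.contributions) == spec.n_datapoints == 50

    def test_suppressing_heterogeneity_inflates_deviance(self):
        # heterogeneous data fitted with tau pinned to ~0 must fit poorly
        cfg = with_seed(default_published_config("continuous"), 17)
        cfg = replace(cfg, tau=0.6)
        bundle = simulate_network(cfg, "continuous")
        mc = MCMCConfig(n_chains=2, n_iter=3000, n_burnin=800, base_seed=8)
        spec_free = build_model(list(bundle.arms), "continuous")
        spec_pinned = build_model(list(bundle.arms), "continuous",
                                  tau_fixed=1e-6)
        dev_free = residual_deviance(fit(spec_free, mc), spec_free)
        dev_pinned = residual_deviance(fit(spec_pinned, mc), spec_pinned)
        assert dev_pinned.D_res > 2.0 * dev_pinned.n_datapoints
        assert dev_pinned.D_res > 2.0 * dev_free.D_res
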