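import math

import numpy as np
import pytest

import mapfdr
from mapfdr.mixture import (
    MixtureDraws,
    McmcConfig,
    MixtureModelSpec,
    effective_sample_size,
    icar_conditional,
)

FAST = McmcConfig(n_chains=2, n_burnin=300, n_store=500, seed=42)


def make_draws(r_draws, theta_draws=None, ids=None):
    """Assemble a MixtureDraws by hand from (chains, draws, areas) arrays."""
    r = np.asarray(r_draws, dtype=np.int8)
    theta = np.ones(r.shape) if theta_draws is None else np.asarray(theta_draws, float)
    ids = ids or [f"A{i}" for i in range(r.shape[2])]
    return MixtureDraws(
        ids, MixtureModelSpec(), McmcConfig(n_store=r.shape[1]),
        {"r": r, "theta": theta, "mu1": np.log(theta), "pi": np.full(r.shape, 0.5)},
        {"sum_r": r.sum(axis=2).astype(float)},
    )


class TestBetaPriorSummary:
    def test_informative_prior_percentiles(self):
        s = mapfdr.beta_prior_summary(9.7, 0.3)
        assert round(s["mean"], 2) == 0.97
        assert round(s["quantiles"][0.10], 2) == 0.91
        assert round(s["quantiles"][0.25], 2) == 0.96
        assert round(s["quantiles"][0.50], 2) == 0.99

    def test_spread_prior_percentiles(self):
        s = mapfdr.beta_prior_summary(9, 1)
        assert round(s["mean"], 2) == 0.90
        got = [round(s["quantiles"][q], 2) for q in (0.1, 0.25, 0.5, 0.75, 0.9)]
        assert got == [0.77, 0.86, 0.93, 0.97, 0.99]

    def test_uniform(self):
        s = mapfdr.beta_prior_summary(1, 1)
        assert s["mean"] == pytest.approx(0.5)
        assert s["quantiles"][0.5] == pytest.approx(0.5)

    def test_invalid_shapes(self):
        with pytest.raises(ValueError):
            mapfdr.beta_prior_summary(0, 1)


class TestGelmanRubin:
    def test_identical_chains(self):
        x = np.sin(np.arange(100.0))
        assert mapfdr.gelman_rubin([x, x]) == pytest.approx(1.0, abs=1e-12)

    def test_offset_chains_diverge(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200)
        assert mapfdr.gelman_rubin([a, a + 100.0]) > 10

    def test_independent_normals_converge(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 10_000))
        assert mapfdr.gelman_rubin(chains) == pytest.approx(1.0, abs=0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            mapfdr.gelman_rubin([[1.0, 2.0]])

    def test_ess_iid_close_to_n(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        assert effective_sample_size(x) == pytest.approx(5000, rel=0.15)


class TestClassificationProbabilities:
    def test_constant_null(self):
        d = make_draws(np.ones((1, 4, 2)))
        p_null, p_inc = mapfdr.classification_probabilities(d)
        assert p_null.tolist() == [1.0, 1.0] and p_inc.tolist() == [0.0, 0.0]

    def test_alternating_mean(self):
        d = make_draws(np.array([[1, 0, 1, 0]]).reshape(1, 4, 1))
        p_null, _ = mapfdr.classification_probabilities(d)
        assert p_null[0] == 0.5

    def test_disagreeing_chains_pool_and_flag(self):
        d = make_draws(np.stack([np.ones((50, 1)), np.zeros((50, 1))]))
        p_null, _ = mapfdr.classification_probabilities(d)
        assert p_null[0] == 0.5
        s = mapfdr.summarize_posterior(d)
        assert s.psrf["sum_r"] > 1.5  # split chains must raise the diagnostic


class TestSummarizePosterior:
    def test_degenerate_draws(self):
        d = make_draws(np.ones((2, 10, 3)))
        s = mapfdr.summarize_posterior(d)
        assert np.allclose(s.frame["rr_mean"], 1.0)
        assert np.allclose(s.frame["rr_low"], s.frame["rr_high"])

    def test_identical_chains_match_single_chain(self):
        rng = np.random.default_rng(4)
        theta = rng.gamma(2.0, 1.0, size=(1, 50, 3))
        r = (rng.random((1, 50, 3)) < 0.5).astype(np.int8)
        one = mapfdr.summarize_posterior(make_draws(r, theta))
        two = mapfdr.summarize_posterior(
            make_draws(np.concatenate([r, r]), np.concatenate([theta, theta])))
        cols = ["rr_mean", "rr_median", "rr_low", "rr_high", "prob_null"]
        assert np.allclose(one.frame[cols], two.frame[cols], rtol=1e-12)

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            mapfdr.summarize_posterior(make_draws(np.ones((1, 4, 1))), level=1.5)


class TestIcarConditional:
    def test_path_graph_moments(self):
        # path A - B - C: middle node conditional is Normal(mean of
        # neighbours, precision lam_v * 2)
        nbrs = [np.array([1]), np.array([0, 2]), np.array([1])]
        mean, prec = icar_conditional([1.0, -5.0, 3.0], nbrs, lam_v=2.0)
        assert mean[1] == pytest.approx(2.0)
        assert prec[1] == pytest.approx(4.0)
        assert mean[0] == pytest.approx(-5.0) and prec[0] == pytest.approx(2.0)

    def test_island_gets_zero_precision(self):
        mean, prec = icar_conditional([1.0, 2.0], [np.array([], dtype=int), np.array([], dtype=int)], 1.0)
        assert prec.tolist() == [0.0, 0.0]


class TestPgSampler:
    def test_seed_reproducibility_bitwise(self, lattice3):
        table, _ = lattice3
        a = mapfdr.fit_mixture(table, cfg=FAST)
        b = mapfdr.fit_mixture(table, cfg=FAST)
        for k in a.per_area:
            assert np.array_equal(a.per_area[k], b.per_area[k])

    def test_chain_label_exchange_invariance(self, lattice3):
        table, _ = lattice3
        d = mapfdr.fit_mixture(table, cfg=FAST)
        swapped = MixtureDraws(d.ids, d.spec, d.config,
                               {k: v[::-1] for k, v in d.per_area.items()},
                               {k: v[::-1] for k, v in d.scalars.items()})
        cols = ["rr_mean", "prob_null", "rr_low", "rr_high"]
        assert np.allclose(mapfdr.summarize_posterior(d).frame[cols],
                           mapfdr.summarize_posterior(swapped).frame[cols],
                           rtol=1e-12)

    def test_conjugate_oracle_null_disabled(self):
        """With the null component off and (k, nu) fixed, the per-area
        posterior of exp(mu1) is Gamma(k + y, nu + e) in closed form."""
        smap = mapfdr.generate_map(n_rows=4, n_cols=5, drop_last=0, seed=9,
                                   e_range=(5, 50), pi0_true=0.9)
        k, nu = 2.0, 1.5
        spec = MixtureModelSpec(fixed_pi=0.0, fixed_k=k, fixed_nu=nu)
        d = mapfdr.fit_mixture(smap.table, spec=spec, cfg=FAST)
        theta = d.pooled("theta")
        n = theta.shape[0]
        y, e = smap.table.y, smap.table.e
        expect = (k + y) / (nu + e)
        se = np.sqrt(k + y) / (nu + e) / math.sqrt(n)
        assert np.all(np.abs(theta.mean(axis=0) - expect) < 3 * se)
        assert np.all(d.pooled("r") == 0)

    def test_prior_mass_recovery(self):
        """With the likelihood masked the chain samples the prior, so the
        across-draw mean of pi_i must return c/(c+d)."""
        table = mapfdr.AreaTable([f"A{i}" for i in range(20)],
                                 np.ones(20), np.ones(20))
        spec = MixtureModelSpec(c=9.7, d=0.3)
        d = mapfdr.fit_mixture(table, spec=spec, cfg=FAST, prior_only=True)
        pi = d.pooled("pi")
        per_draw = pi.mean(axis=1)
        ess = effective_sample_size(per_draw.reshape(d.n_chains, -1))
        se = per_draw.std(ddof=1) / math.sqrt(ess)
        assert abs(pi.mean() - 9.7 / 10.0) < 3 * se + 1e-4

    def test_null_prior_dominates_on_null_data(self):
        smap = mapfdr.generate_map(n_rows=5, n_cols=5, drop_last=0,
                                   pi0_true=1.0, seed=13, e_range=(5, 50))
        spec = MixtureModelSpec(c=97, d=3)
        d = mapfdr.fit_mixture(smap.table, spec=spec, cfg=FAST)
        p_null, _ = mapfdr.classification_probabilities(d)
        assert np.all(p_null > 0.5)

    def test_shrinkage_toward_null_on_null_map(self):
        smap = mapfdr.generate_map(n_rows=6, n_cols=6, drop_last=0,
                                   pi0_true=1.0, seed=21, e_range=(0.5, 20))
        d = mapfdr.fit_mixture(smap.table, cfg=FAST)
        s = mapfdr.summarize_posterior(d)
        smr = mapfdr.compute_smr(smap.table).smr
        extreme = (smap.table.e < 5) & (np.abs(smr - 1) > 0.3)
        assert extreme.any()
        post = s.frame["rr_mean"].to_numpy()
        assert np.all(np.abs(post[extreme] - 1) <= np.abs(smr[extreme] - 1))

    def test_common_pi_mode_runs(self, lattice3):
        table, _ = lattice3
        spec = MixtureModelSpec(pi_sharing="common")
        d = mapfdr.fit_mixture(table, spec=spec, cfg=FAST)
        pi = d.per_area["pi"]
        # a shared pi is constant across areas within each draw
        assert np.allclose(pi.max(axis=2), pi.min(axis=2))


class TestBymSampler:
    def test_requires_adjacency(self, lattice3):
        table, _ = lattice3
        with pytest.raises(ValueError, match="adjacency"):
            mapfdr.fit_mixture(table, spec=MixtureModelSpec(variant="bym"), cfg=FAST)

    def test_runs_and_centres_v(self, lattice3):
        table, adj = lattice3
        d = mapfdr.fit_mixture(table, adj, MixtureModelSpec(variant="bym"), FAST)
        s = mapfdr.summarize_posterior(d)
        assert np.all((0 <= s.frame["prob_null"]) & (s.frame["prob_null"] <= 1))
        assert {"lam_u", "lam_v"} <= set(d.scalars)

    def test_island_warns_and_pins_spatial_term(self):
        ids, adj = mapfdr.lattice_adjacency(2, 2)
        ids = ids + ["ISL"]
        nbrs = {k: set(v) for k, v in adj.neighbours.items()}
        nbrs["ISL"] = set()
        table = mapfdr.AreaTable(ids, np.ones(5), np.ones(5))
        with pytest.warns(UserWarning, match="no neighbours"):
            d = mapfdr.fit_mixture(table, mapfdr.AdjacencyMap(nbrs),
                                   MixtureModelSpec(variant="bym"), FAST)
        assert d.per_area["theta"].shape[-1] == 5

    def test_icar_sampled_conditional_moments(self):
        """Sampling the middle node of a 3-node path with fixed neighbours
        reproduces Normal(neighbour mean, lam_v * n_i) moments."""
        rng = np.random.default_rng(8)
        nbrs = [np.array([1]), np.array([0, 2]), np.array([1])]
        v = np.array([1.0, 0.0, 3.0])
        lam_v = 2.5
        mean, prec = icar_conditional(v, nbrs, lam_v)
        draws = mean[1] + rng.standard_normal(100_000) / math.sqrt(prec[1])
        assert draws.mean() == pytest.approx(2.0, abs=0.02)
        assert 1.0 / draws.var() == pytest.approx(lam_v * 2, rel=0.02)


class TestSensitivitySweep:
    def test_singleton_sweep_matches_single_fit(self, lattice3):
        table, _ = lattice3
        spec = MixtureModelSpec()
        sweep = mapfdr.sensitivity_sweep(table, None, spec, [(9.7, 0.3)], FAST)
        direct = mapfdr.summarize_posterior(mapfdr.fit_mixture(table, None, spec, FAST))
        assert sweep.summaries[(9.7, 0.3)].frame.equals(direct.frame)

    def test_qq_pairs_sorted(self, lattice3):
        table, _ = lattice3
        sweep = mapfdr.sensitivity_sweep(table, None, MixtureModelSpec(),
                                         [(9.7, 0.3), (1.0, 1.0)], FAST)
        pairs = sweep.qq_pairs((9.7, 0.3), (1.0, 1.0))
        assert pairs.shape == (table.m, 2)
        assert np.all(np.diff(pairs[:, 0]) >= 0)
        assert -1.0 <= sweep.rank_correlation((9.7, 0.3), (1.0, 1.0)) <= 1.0
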