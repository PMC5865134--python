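"""BYM model machinery: ICAR conditionals, the sampler, diagnostics, DIC."""

import math

import numpy as np
import pandas as pd
import pytest

from carmap import (
    MCMCConfig,
    NeighborStructure,
    PosteriorChains,
    bgr_trajectory,
    compute_dic,
    fit_bym,
    gelman_rubin,
    generate_lattice,
    generate_population,
    icar_full_conditional,
    indirect_standardise,
    mc_error,
    poisson_log_likelihood,
    simulate_counts,
    summarize_posterior,
)
from carmap.synthetic import SimulationTruth


def _null_dataset(seed, rows=4, cols=5, pop_range=(20_000, 60_000)):
    lat = generate_lattice(rows, cols)
    ns = lat.queen_neighbors()
    pop = generate_population(lat, pop_range, seed)
    n = lat.n_regions
    truth = SimulationTruth(tau_u=1.0, tau_v=1.0, u=np.zeros(n), v=np.zeros(n))
    sim = simulate_counts(pop, truth, None, seed + 1)
    return indirect_standardise(sim.stratum_cases, pop), ns


def _chains_from_mu(mu, expected=None):
    """Minimal PosteriorChains wrapper around given mu draws (1 chain x K x n)."""
    mu = np.asarray(mu, dtype=float)
    c, k, n = mu.shape
    z = np.zeros((c, k))
    zn = np.zeros((c, k, n))
    return PosteriorChains(
        region_ids=[f"r{i}" for i in range(n)],
        beta_names=[],
        expected=np.ones(n) if expected is None else np.asarray(expected, float),
        alpha=z, beta=np.zeros((c, k, 0)), u=zn, v=zn,
        tau_u=z + 1, tau_v=z + 1, mu=mu,
    )


class TestICARConditional:
    def test_neighbour_mean_and_variance(self):
        ns = NeighborStructure(["a", "b", "c"], [[1, 2], [0], [0]])
        u = np.array([0.0, 0.2, 0.4])
        mean, var = icar_full_conditional(u, 0, ns, tau_u=1.0)
        assert mean == pytest.approx(0.3)
        assert var == pytest.approx(0.5)

    def test_zero_neighbours_give_zero_mean(self):
        ns = NeighborStructure(["a", "b", "c"], [[1, 2], [0], [0]])
        mean, _ = icar_full_conditional(np.zeros(3), 0, ns, tau_u=7.0)
        assert mean == 0.0

    def test_variance_vanishes_with_tau(self):
        ns = NeighborStructure(["a", "b"], [[1], [0]])
        _, var = icar_full_conditional(np.array([0.0, 1.0]), 0, ns, tau_u=1e12)
        assert var < 1e-11

    def test_matches_dense_precision_oracle(self):
        # conditional of a Gaussian with precision Q = tau*(D-W):
        # mean_i = -Q_ii^{-1} sum_{j!=i} Q_ij u_j, var_i = 1/Q_ii
        ns = generate_lattice(2, 3).queen_neighbors()
        tau = 2.5
        q = tau * ns.laplacian()
        rng = np.random.default_rng(0)
        u = rng.normal(size=ns.n)
        for i in range(ns.n):
            mean, var = icar_full_conditional(u, i, ns, tau)
            others = [j for j in range(ns.n) if j != i]
            assert mean == pytest.approx(-(q[i, others] @ u[others]) / q[i, i])
            assert var == pytest.approx(1.0 / q[i, i])

    def test_island_rejected(self):
        ns = NeighborStructure(["a", "b", "c"], [[1], [0], []])
        with pytest.raises(ValueError, match="island"):
            icar_full_conditional(np.zeros(3), 2, ns, 1.0)


def test_poisson_loglik_matches_brute_force():
    rng = np.random.default_rng(3)
    O = rng.poisson(5.0, size=10).astype(float)
    mu = rng.uniform(0.5, 10.0, size=10)
    brute = sum(
        o * math.log(m) - m - math.log(math.factorial(int(o))) for o, m in zip(O, mu)
    )
    assert poisson_log_likelihood(O, mu) == pytest.approx(brute, abs=1e-10)


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        x = np.random.default_rng(0).normal(size=1000)
        assert gelman_rubin(np.stack([x, x])) == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert gelman_rubin(chains) > 10

    def test_same_stationary_distribution_converged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 5000))
        assert gelman_rubin(chains) < 1.05

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_bgr_trajectory_runs_on_prefixes(self):
        rng = np.random.default_rng(3)
        traj = bgr_trajectory(rng.normal(size=(2, 2000)), n_points=10)
        assert traj.n_draws.is_monotonic_increasing
        assert traj.n_draws.iloc[-1] == 2000
        assert (traj.rhat > 0.9).all()


class TestMCError:
    def test_iid_matches_root_n(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10_000)
        assert mc_error(x) == pytest.approx(x.std() / np.sqrt(x.size), rel=0.30)

    def test_constant_draws_zero(self):
        assert mc_error(np.full(1000, 3.14)) == pytest.approx(0.0, abs=1e-12)

    def test_autocorrelation_inflates_error(self):
        rng = np.random.default_rng(5)
        n, phi = 20_000, 0.95
        ar = np.empty(n)
        ar[0] = rng.normal()
        for t in range(1, n):
            ar[t] = phi * ar[t - 1] + rng.normal()
        assert mc_error(ar) > ar.std() / np.sqrt(n) * 2

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            mc_error(np.zeros(50))


class TestDIC:
    def test_degenerate_posterior_has_zero_pd(self):
        mu = np.tile([[2.0, 3.0]], (1, 50, 1)).reshape(1, 50, 2)
        cases = pd.DataFrame({"observed": [2, 3]})
        res = compute_dic(_chains_from_mu(mu), cases)
        assert res.pd == pytest.approx(0.0, abs=1e-10)
        assert res.dic == pytest.approx(res.dbar)
        assert res.dic == pytest.approx(2 * res.dbar - res.d_hat)

    def test_two_draw_toy_matches_hand_computation(self):
        # one region, O=2, mu in {1, 3}
        def dev(mu):
            return -2 * (2 * math.log(mu) - mu - math.log(2))

        mu = np.array([1.0, 3.0]).reshape(1, 2, 1)
        cases = pd.DataFrame({"observed": [2]})
        res = compute_dic(_chains_from_mu(mu), cases)
        dbar = (dev(1.0) + dev(3.0)) / 2
        d_hat = dev(2.0)
        assert res.dbar == pytest.approx(dbar, abs=1e-12)
        assert res.d_hat == pytest.approx(d_hat, abs=1e-12)
        assert res.dic == pytest.approx(2 * dbar - d_hat, abs=1e-12)

    def test_nonpositive_mu_rejected(self):
        mu = np.array([1.0, -1.0]).reshape(1, 2, 1)
        with pytest.raises(ValueError):
            compute_dic(_chains_from_mu(mu), pd.DataFrame({"observed": [2]}))


class TestSummarize:
    def test_degenerate_chains_zero_width(self):
        mu = np.full((1, 200, 3), 2.0)
        s = summarize_posterior(_chains_from_mu(mu, expected=[1.0, 2.0, 4.0]))
        assert list(s.sir) == [2.0, 1.0, 0.5]
        assert (s.upper - s.lower == 0).all()

    def test_percentile_rule_on_known_draws(self):
        draws = np.arange(1, 1001, dtype=float) / 100.0
        mu = draws.reshape(1, 1000, 1)
        s = summarize_posterior(_chains_from_mu(mu))
        # linear-interpolation order statistics on 1..1000 over 100
        assert s.sir[0] == pytest.approx(5.005)
        assert s.lower[0] == pytest.approx(0.25975)
        assert s.upper[0] == pytest.approx(9.75025)

    def test_elevated_needs_strictly_above_one(self):
        # 2.5th percentile lands exactly on 1.0 -> not flagged (strict rule)
        draws = np.concatenate([np.ones(50), np.linspace(1.5, 3.0, 950)])
        s = summarize_posterior(_chains_from_mu(draws.reshape(1, 1000, 1)))
        assert s.lower[0] == 1.0
        assert bool(s.elevated[0]) is False


class TestFitBYM:
    def test_reproducible_and_sum_to_zero(self):
        cases, ns = _null_dataset(seed=10)
        cfg = MCMCConfig.desk(seed=1, burn_in=500, iterations=2000)
        a = fit_bym(cases, ns, None, cfg)
        b = fit_bym(cases, ns, None, cfg)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.mu, b.mu)
        # every stored draw of u sums to ~0 (single component)
        assert np.abs(a.u.sum(axis=2)).max() < 1e-9

    def test_seed_stability_within_mc_error(self):
        cases, ns = _null_dataset(seed=11)
        cfg1 = MCMCConfig.desk(seed=1, burn_in=2000, iterations=10_000)
        cfg2 = MCMCConfig.desk(seed=2, burn_in=2000, iterations=10_000)
        a = fit_bym(cases, ns, None, cfg1)
        b = fit_bym(cases, ns, None, cfg2)
        for name in ("intercept", "tau_u"):
            xa, xb = a.pooled(name), b.pooled(name)
            tol = 3 * np.hypot(mc_error(xa), mc_error(xb))
            assert abs(xa.mean() - xb.mean()) <= tol

    def test_shrinkage_towards_one_for_small_regions(self):
        # low-E regions: smoothing should pull the SIR towards 1 vs crude
        wins = trials = 0
        for seed in range(12):
            cases, ns = _null_dataset(seed=100 + seed, pop_range=(500, 2000))
            cfg = MCMCConfig.desk(seed=seed, burn_in=500, iterations=2000)
            chains = fit_bym(cases, ns, None, cfg)
            s = summarize_posterior(chains)
            i = int(cases.expected.idxmin())
            crude = cases.crude_sir[i]
            smooth = s.sir[i]
            trials += 1
            wins += abs(smooth - 1.0) < abs(crude - 1.0)
        assert wins / trials >= 0.9

    def test_strong_signal_region_flagged(self):
        cases, ns = _null_dataset(seed=12)
        cases = cases.copy()
        cases.loc[7, "observed"] = int(5 * cases.loc[7, "expected"])
        chains = fit_bym(cases, ns, None, MCMCConfig.desk(seed=3, burn_in=1000, iterations=4000))
        s = summarize_posterior(chains)
        assert bool(s.elevated[7]) is True

    def test_rejects_bad_inputs(self):
        cases, ns = _null_dataset(seed=13)
        bad = cases.copy()
        bad.loc[0, "expected"] = 0.0
        with pytest.raises(ValueError, match="expected"):
            fit_bym(bad, ns, None, MCMCConfig.desk(seed=0, burn_in=10, iterations=20))
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError):
            summarize_posterior(_chains_from_mu(np.zeros((1, 0, 2))))
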