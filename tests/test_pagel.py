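"""Likelihood machinery for the correlated-evolution test."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.linalg import null_space

from cooccurevo.pagel import (
    MCMCConfig,
    PruningLikelihood,
    RateParamsDependent,
    RateParamsIndependent,
    compute_bf,
    fit_ml,
    marginal_loglik,
    mcmc_sample,
    pruning_loglik,
    rate_matrix,
    stationary_distribution,
    transition_probs,
)
from cooccurevo.synthetic import (
    DEFAULT_DEPENDENT_RATES,
    simulate_traits,
    simulate_tree,
)
from cooccurevo.traits import TraitMatrix
from cooccurevo.trees import read_newick

from oracles import enumerate_loglik, grid_search_rate


def random_dep_params(rng):
    return RateParamsDependent(*rng.exponential(1.0, 8))


class TestRateMatrix:
    def test_rows_sum_to_zero(self, rng):
        for _ in range(10):
            Q = rate_matrix(random_dep_params(rng))
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_double_transitions_forbidden(self, rng):
        # 00 <-> 11 and 01 <-> 10 change both traits at once
        for _ in range(10):
            Q = rate_matrix(random_dep_params(rng))
            assert Q[0, 3] == 0 and Q[3, 0] == 0
            assert Q[1, 2] == 0 and Q[2, 1] == 0

    def test_independent_embedding_entries(self):
        p = RateParamsIndependent(ax=0.3, bx=1.1, ay=0.7, by=0.2)
        Q = rate_matrix(p)
        # states (00, 01, 10, 11); x-transitions: 00<->10, 01<->11
        assert Q[0, 2] == Q[1, 3] == p.ax
        assert Q[2, 0] == Q[3, 1] == p.bx
        # y-transitions: 00<->01, 10<->11
        assert Q[0, 1] == Q[2, 3] == p.ay
        assert Q[1, 0] == Q[3, 2] == p.by

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            RateParamsIndependent(-0.1, 1, 1, 1)


class TestTransitionProbs:
    def test_zero_time_is_identity(self, rng):
        Q = rate_matrix(random_dep_params(rng))
        assert np.allclose(transition_probs(Q, 0.0), np.eye(4))

    def test_symmetric_two_state_closed_form(self):
        # marginal of one trait with symmetric rates q: P(stay) = (1+exp(-2qt))/2
        q, t = 0.7, 1.3
        Q = rate_matrix(RateParamsIndependent(q, q, 0.0, 0.0))
        P = transition_probs(Q, t)
        stay = 0.5 * (1 + math.exp(-2 * q * t))
        assert P[0, 0] == pytest.approx(stay, abs=1e-12)
        assert P[0, 2] == pytest.approx(1 - stay, abs=1e-12)

    def test_long_time_reaches_stationary(self, rng):
        params = random_dep_params(rng)
        Q = rate_matrix(params)
        # independent oracle: null space of Q^T
        ns = null_space(Q.T)
        pi = np.abs(ns[:, 0]) / np.abs(ns[:, 0]).sum()
        P = transition_probs(Q, 1e4 / np.abs(Q).max())
        for row in P:
            assert row == pytest.approx(pi, abs=1e-6)
        assert stationary_distribution(Q) == pytest.approx(pi, abs=1e-9)

    def test_negative_time_rejected(self):
        Q = rate_matrix(RateParamsIndependent(1, 1, 1, 1))
        with pytest.raises(ValueError):
            transition_probs(Q, -0.1)


class TestPruningLikelihood:
    def test_matches_enumeration_on_small_trees(self, rng):
        newicks = [
            "(A:0.5,B:1.2);",
            "((A:0.3,B:0.6):0.4,C:0.9);",
            "((A:0.2,B:0.8):0.3,(C:0.5,D:0.1):0.7);",
        ]
        for nwk in newicks:
            tree = read_newick(nwk)
            labels = tree.tip_labels
            for _ in range(10):
                Q = rate_matrix(random_dep_params(rng))
                states = {lab: (int(rng.integers(2)), int(rng.integers(2)))
                          for lab in labels}
                tm = TraitMatrix(states)
                got = pruning_loglik(tree, tm, Q)
                want = enumerate_loglik(tree, tm, Q)
                assert got == pytest.approx(want, abs=1e-10)

    def test_missing_data_marginalized(self, rng):
        tree = read_newick("((A:0.3,B:0.6):0.4,C:0.9);")
        Q = rate_matrix(random_dep_params(rng))
        tm = TraitMatrix({"A": (1, None), "B": (0, 0), "C": (None, None)})
        got = pruning_loglik(tree, tm, Q)
        want = enumerate_loglik(tree, tm, Q)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_branch_lengths_force_root_state(self):
        tree = read_newick("((A:0,B:0):0,C:0);")
        Q = rate_matrix(RateParamsIndependent(1, 1, 1, 1))
        tm = TraitMatrix({t: (1, 1) for t in "ABC"})
        assert pruning_loglik(tree, tm, Q) == pytest.approx(math.log(0.25))

    def test_total_probability_is_one(self, five_tip_tree, rng):
        Q = rate_matrix(random_dep_params(rng))
        labels = five_tip_tree.tip_labels
        total = 0.0
        for states in itertools.product(range(4), repeat=5):
            tm = TraitMatrix({lab: (s >> 1, s & 1)
                              for lab, s in zip(labels, states)})
            total += math.exp(pruning_loglik(five_tip_tree, tm, Q))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_tip_reordering_and_child_swap(self, rng):
        Q = rate_matrix(random_dep_params(rng))
        states = {"A": (1, 0), "B": (0, 1), "C": (1, 1), "D": (0, 0)}
        t1 = read_newick("((A:0.2,B:0.8):0.3,(C:0.5,D:0.1):0.7);")
        t2 = read_newick("((D:0.1,C:0.5):0.7,(B:0.8,A:0.2):0.3);")
        ll1 = pruning_loglik(t1, TraitMatrix(states), Q)
        ll2 = pruning_loglik(t2, TraitMatrix(states), Q)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_nesting_identity(self, five_tip_tree, five_tip_traits, rng):
        for _ in range(10):
            ind = RateParamsIndependent(*rng.exponential(1.0, 4))
            ll_ind = pruning_loglik(five_tip_tree, five_tip_traits,
                                    rate_matrix(ind))
            ll_emb = pruning_loglik(five_tip_tree, five_tip_traits,
                                    rate_matrix(ind.embed()))
            assert ll_ind == pytest.approx(ll_emb, abs=1e-10)

    def test_trait_tree_mismatch_raises(self, five_tip_tree):
        tm = TraitMatrix({"A": (0, 0), "B": (1, 1)})
        with pytest.raises(ValueError, match="do not match"):
            pruning_loglik(five_tip_tree, tm, rate_matrix(
                RateParamsIndependent(1, 1, 1, 1)))


class TestFitML:
    def test_dependent_fit_at_least_independent(self):
        tree = simulate_tree(40, 1.0, 11)
        tm = simulate_traits(tree, DEFAULT_DEPENDENT_RATES, "dependent",
                             (0, 0), 12)
        ind = fit_ml(tree, tm, "independent", n_starts=3, seed=0)
        dep = fit_ml(tree, tm, "dependent", n_starts=3, seed=0)
        assert dep.loglik >= ind.loglik - 1e-6

    def test_constrained_dependent_reproduces_independent_loglik(
            self, five_tip_tree, five_tip_traits):
        ind = fit_ml(five_tip_tree, five_tip_traits, "independent",
                     n_starts=3, seed=1)
        like = PruningLikelihood(five_tip_tree, five_tip_traits)
        assert like.loglik(ind.rates.embed()) == pytest.approx(
            ind.loglik, abs=1e-8)

    def test_one_free_rate_matches_grid_search(self):
        tree = read_newick("(A:1.0,B:1.0);")
        tm = TraitMatrix({"A": (1, 0), "B": (0, 0)})
        fixed = {"bx": 0.4, "ay": 0.2, "by": 0.2}
        like = PruningLikelihood(tree, tm)

        def ll(ax):
            return like.loglik(RateParamsIndependent(ax, 0.4, 0.2, 0.2))

        q_grid, _ = grid_search_rate(ll, 1e-4, 50.0)
        fit = fit_ml(tree, tm, "independent", n_starts=4, seed=2,
                     fixed_rates=fixed)
        assert fit.rates.ax == pytest.approx(q_grid, abs=1e-4)


class TestMCMC:
    def test_identical_seed_identical_chain(self, five_tip_tree, five_tip_traits):
        cfg = MCMCConfig(chain_length=300, burn_in=100, seed=7)
        s1 = mcmc_sample(five_tip_tree, five_tip_traits, "independent", cfg)
        s2 = mcmc_sample(five_tip_tree, five_tip_traits, "independent", cfg)
        assert np.array_equal(s1.rates, s2.rates)

    def test_prior_recovered_without_data(self, two_tip_tree):
        # all tips missing -> posterior is the exponential(10) prior
        tm = TraitMatrix({"A": (None, None), "B": (None, None)})
        cfg = MCMCConfig(chain_length=6000, burn_in=1000, seed=3)
        s = mcmc_sample(two_tip_tree, tm, "independent", cfg)
        for j in range(4):
            x = s.rates[:, j]
            se = x.std(ddof=1) / math.sqrt(max(s.ess[j], 1.0))
            assert abs(x.mean() - cfg.prior_mean) < 3 * max(se, 0.5)

    def test_acceptance_rate_reasonable_on_simulated_data(self):
        tree = simulate_tree(100, 1.0, 21)
        tm = simulate_traits(tree, DEFAULT_DEPENDENT_RATES, "dependent",
                             (0, 0), 22)
        cfg = MCMCConfig(chain_length=800, burn_in=300, seed=5)
        s = mcmc_sample(tree, tm, "dependent", cfg)
        assert 0.1 < s.acceptance_rate < 0.7

    def test_invalid_config(self):
        with pytest.raises(ValueError, match="chain_length"):
            MCMCConfig(chain_length=100, burn_in=100)
        with pytest.raises(ValueError, match="n_stones"):
            MCMCConfig(n_stones=2)


class TestMarginalLik:
    def test_all_rates_fixed_equals_loglik(self, two_tip_tree):
        tm = TraitMatrix({"A": (1, 0), "B": (0, 0)})
        fixed = {"ax": 0.7, "bx": 0.5, "ay": 0.3, "by": 0.3}
        cfg = MCMCConfig(chain_length=200, burn_in=50, seed=1)
        mz = marginal_loglik(two_tip_tree, tm, "independent", cfg,
                             fixed_rates=fixed)
        like = PruningLikelihood(two_tip_tree, tm)
        assert mz.logz == like.loglik(RateParamsIndependent(0.7, 0.5, 0.3, 0.3))
        assert mz.se == 0.0

    def test_matches_quadrature_one_free_rate(self, two_tip_tree):
        tm = TraitMatrix({"A": (1, 0), "B": (0, 0)})
        fixed = {"bx": 0.5, "ay": 0.3, "by": 0.3}
        like = PruningLikelihood(two_tip_tree, tm)
        m = 10.0

        def integrand(q):
            return math.exp(like.loglik(
                RateParamsIndependent(q, 0.5, 0.3, 0.3))) * math.exp(-q / m) / m

        val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
        cfg = MCMCConfig(chain_length=2500, burn_in=500, n_stones=16, seed=11)
        mz = marginal_loglik(two_tip_tree, tm, "independent", cfg,
                             fixed_rates=fixed)
        assert abs(mz.logz - math.log(val)) < 2 * mz.se

    def test_stone_count_self_consistency(self, five_tip_tree, five_tip_traits):
        cfg8 = MCMCConfig(chain_length=1200, burn_in=300, n_stones=8, seed=4)
        cfg32 = MCMCConfig(chain_length=1200, burn_in=300, n_stones=32, seed=5)
        z8 = marginal_loglik(five_tip_tree, five_tip_traits, "independent", cfg8)
        z32 = marginal_loglik(five_tip_tree, five_tip_traits, "independent", cfg32)
        se = math.hypot(z8.se, z32.se)
        assert abs(z8.logz - z32.logz) < 3 * se


class TestBayesFactor:
    @pytest.mark.parametrize("bf,band", [
        (9.7, "strong"),
        (1.0, "weak"),
        (12.0, "very strong"),
        (2.0, "positive"),
        (4.99, "positive"),
        (5.0, "strong"),
        (10.0, "strong"),
        (-3.0, "weak"),
    ])
    def test_bands(self, bf, band):
        got_bf, got_band = compute_bf(bf / 2.0, 0.0)
        assert got_bf == pytest.approx(bf)
        assert got_band == band

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            compute_bf(float("nan"), 0.0)
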