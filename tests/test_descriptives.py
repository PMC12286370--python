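import itertools

import numpy as np
import pytest

from swipenet import (
    DirectedBipartiteNetwork,
    cohens_d_from_moments,
    degree_summary,
    degrees,
    density,
    gender_gap,
    indegree_centralization,
    reciprocity,
    standardize_degrees,
)
from swipenet.descriptives import UndefinedMeasureError, _skewness

import _oracles
from conftest import random_net


class TestDegrees:
    def test_net_a_indegrees(self, net_a):
        assert degrees(net_a, "women", "in").to_dict() == {"w1": 2.0}
        assert degrees(net_a, "men", "in").to_dict() == {"m1": 1.0, "m2": 0.0}

    def test_net_a_outdegrees(self, net_a):
        assert degrees(net_a, "women", "out").to_dict() == {"w1": 1.0}
        assert degrees(net_a, "men", "out").to_dict() == {"m1": 1.0, "m2": 1.0}

    def test_unknown_mode_or_direction(self, net_a):
        with pytest.raises(ValueError, match="mode"):
            degrees(net_a, "aliens", "in")
        with pytest.raises(ValueError, match="direction"):
            degrees(net_a, "men", "sideways")

    def test_standardized_values(self, net_a):
        std_w = standardize_degrees(net_a, "women", "in")
        assert std_w["w1"] == pytest.approx(2 / 2)  # swiped by all men
        std_m = standardize_degrees(net_a, "men", "in")
        assert std_m["m2"] == 0.0

    def test_standardized_empty_opposite_mode(self):
        net = DirectedBipartiteNetwork(["w1"], [], np.zeros((1, 0)), np.zeros((0, 1)))
        with pytest.raises(UndefinedMeasureError):
            standardize_degrees(net, "women", "in")

    def test_conservation_sum_in_equals_sum_out(self):
        """Total indegree = total outdegree = total ties, every network."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            net = random_net(rng)
            tot_in = degrees(net, "all", "in").sum()
            tot_out = degrees(net, "all", "out").sum()
            assert tot_in == tot_out == net.total_ties


class TestDegreeSummary:
    def test_net_a_men_indegree_summary(self, net_a):
        s = degree_summary(net_a, "men", "in")
        assert (s.mean, s.median, s.max) == (0.5, 0.5, 1.0)
        assert s.total == 1.0

    def test_constant_vector_has_zero_sd_and_skew(self):
        net = DirectedBipartiteNetwork(
            ["w1", "w2"], ["m1"], np.zeros((2, 1)), np.ones((1, 2))
        )
        s = degree_summary(net, "women", "in")
        assert s.sd == 0.0 and s.skewness == 0.0

    def test_skewness_matches_direct_moment_computation(self):
        rng = np.random.default_rng(3)
        x = rng.negative_binomial(1, 0.2, size=200).astype(float)
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        assert _skewness(x) == pytest.approx(m3 / m2**1.5)
        assert _skewness(x) > 0  # right-skewed count law


class TestDensity:
    def test_net_a(self, net_a):
        assert density(net_a) == pytest.approx(3 / (1 * 2 * 2))

    def test_complete_mutual_network_is_one(self):
        net = DirectedBipartiteNetwork(
            ["w1", "w2"], ["m1", "m2"], np.ones((2, 2)), np.ones((2, 2))
        )
        assert density(net) == 1.0

    def test_empty_mode_raises(self):
        net = DirectedBipartiteNetwork([], ["m1"], np.zeros((0, 1)), np.zeros((1, 0)))
        with pytest.raises(UndefinedMeasureError):
            density(net)

    def test_mode_swap_invariance(self):
        """Density is unchanged when the two modes swap roles."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            net = random_net(rng)
            swapped = DirectedBipartiteNetwork(
                women=net.men, men=net.women, M_F=net.M_M, M_M=net.M_F
            )
            assert density(net) == pytest.approx(density(swapped))


class TestCentralization:
    def test_net_a_men_perfect_star(self, net_a):
        assert indegree_centralization(net_a, "men") == pytest.approx(1.0)

    def test_equal_indegrees_give_zero(self):
        net = DirectedBipartiteNetwork(
            ["w1", "w2"], ["m1", "m2"], np.zeros((2, 2)), np.ones((2, 2))
        )
        assert indegree_centralization(net, "women") == 0.0

    def test_bipartite_in_star_is_one(self):
        M_M = np.zeros((3, 4), dtype=np.int8)
        M_M[:, 0] = 1  # every man swipes woman 0 only
        net = DirectedBipartiteNetwork(
            [f"w{i}" for i in range(4)], [f"m{i}" for i in range(3)],
            np.zeros((4, 3)), M_M,
        )
        assert indegree_centralization(net, "women") == pytest.approx(1.0)

    def test_mode_size_one_raises(self, net_a):
        with pytest.raises(UndefinedMeasureError):
            indegree_centralization(net_a, "women")

    def test_tie_preserving_variant_agrees_when_star_feasible(self, net_a):
        # T=1 tie <= 1 opposite node, so both denominators describe
        # the same feasible star
        a = indegree_centralization(net_a, "men", denominator="star")
        b = indegree_centralization(net_a, "men", denominator="tie_preserving")
        assert a == b == 1.0


class TestReciprocity:
    def test_net_a(self, net_a):
        assert reciprocity(net_a) == pytest.approx(2 / 3)

    def test_no_mutual_pairs(self):
        net = DirectedBipartiteNetwork(
            ["w1"], ["m1", "m2"], np.array([[1, 0]]), np.array([[0], [1]])
        )
        assert reciprocity(net) == 0.0

    def test_quarter_of_swipes_matched(self):
        # 1 match (2 ties) out of 8 ties -> 0.25
        M_F = np.array([[1, 1, 1, 0]])
        M_M = np.array([[1], [0], [0], [0]])
        net = DirectedBipartiteNetwork(
            ["w1", "w2", "w3", "w4"],
            ["m1", "m2", "m3", "m4"],
            np.vstack([M_F, np.array([[1, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0]])]),
            np.hstack([M_M, np.zeros((4, 3), dtype=np.int8)]),
        )
        assert net.total_ties == 8
        assert reciprocity(net) == pytest.approx(0.25)

    def test_tieless_network_raises(self):
        net = DirectedBipartiteNetwork(["w1"], ["m1"], np.zeros((1, 1)), np.zeros((1, 1)))
        with pytest.raises(UndefinedMeasureError):
            reciprocity(net)


class TestBruteForceAgreement:
    """All measures vs naive edge-list recomputation on random networks."""

    def test_measures_match_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            net = random_net(rng)
            edges = net.edges()
            if net.total_ties == 0:
                continue
            assert density(net) == pytest.approx(
                _oracles.naive_density(edges, net.n_women, net.n_men)
            )
            assert reciprocity(net) == pytest.approx(_oracles.naive_reciprocity(edges))
            oracle_deg = _oracles.naive_degrees(edges, net.women, net.men)
            for mode in ("women", "men"):
                got = degrees(net, mode, "in").to_dict()
                ids = net.women if mode == "women" else net.men
                assert got == {n: float(oracle_deg["in"][n]) for n in ids}
            if net.n_women >= 2:
                assert indegree_centralization(net, "women") == pytest.approx(
                    _oracles.naive_centralization(edges, net.women, net.men)
                )

    def test_bounds_zero_one(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            net = random_net(rng)
            assert 0 <= density(net) <= 1
            if net.total_ties:
                assert 0 <= reciprocity(net) <= 1
            for mode in ("women", "men"):
                assert standardize_degrees(net, mode, "in").between(0, 1).all()
                if (net.n_women if mode == "women" else net.n_men) >= 2:
                    assert 0 <= indegree_centralization(net, mode) <= 1


class TestGenderGap:
    def test_identical_distributions_give_zero_d(self):
        # every woman swiped by all men and vice versa: both modes have
        # constant standardized indegree 1 -> zero pooled SD -> error
        net = DirectedBipartiteNetwork(
            ["w1", "w2"], ["m1", "m2"], np.ones((2, 2)), np.ones((2, 2))
        )
        with pytest.raises(UndefinedMeasureError):
            gender_gap(net, n_permutations=10, seed=0)

    def test_symmetric_spread_gives_small_d_large_p(self):
        # women std indegrees {0,1}, men std indegrees {0,1}: same
        # distribution in both groups -> d = 0, p = 1
        M_M = np.array([[1, 0], [1, 0]])  # w1 swiped by both men, w2 by none
        M_F = np.array([[1, 0], [1, 0]])  # m1 swiped by both women
        net = DirectedBipartiteNetwork(["w1", "w2"], ["m1", "m2"], M_F, M_M)
        res = gender_gap(net, n_permutations=500, seed=1)
        assert res.cohens_d == 0.0
        assert res.p_value == 1.0

    def test_zero_pooled_sd_raises(self):
        """Groups {0,0} vs {1,1} have no within-group spread: d is
        undefined and reported as such."""
        M_M = np.array([[0, 0], [0, 0]])  # women receive nothing
        M_F = np.array([[1, 1], [1, 1]])  # men receive everything
        net = DirectedBipartiteNetwork(["w1", "w2"], ["m1", "m2"], M_F, M_M)
        with pytest.raises(UndefinedMeasureError, match="pooled"):
            gender_gap(net, n_permutations=10, seed=0)

    def test_permutation_p_matches_exact_enumeration(self):
        """Two-point groups: the exact two-sided p over all label
        splits is 1/3, and the sampled p converges to it."""
        M_M = np.array([[1, 0], [0, 0]])  # women std indegrees {0.5, 0}
        M_F = np.array([[1, 1], [1, 1]])  # men std indegrees {1, 1}
        net = DirectedBipartiteNetwork(["w1", "w2"], ["m1", "m2"], M_F, M_M)
        std_w = [0.5, 0.0]
        std_m = [1.0, 1.0]
        pooled = std_w + std_m
        obs = abs(np.mean(std_w) - np.mean(std_m))
        exact = np.mean(
            [
                abs(np.mean(p[:2]) - np.mean(p[2:])) >= obs - 1e-12
                for p in itertools.permutations(pooled)
            ]
        )
        assert exact == pytest.approx(1 / 3)
        res = gender_gap(net, n_permutations=6000, seed=2)
        assert res.p_value == pytest.approx(exact, abs=0.03)
        assert res.cohens_d < 0  # men more desirable here

    def test_seed_required(self, net_a):
        with pytest.raises(ValueError, match="seed"):
            gender_gap(net_a)


def test_cohens_d_from_moments_simple():
    # equal SDs: d = mean difference / common SD
    assert cohens_d_from_moments(2.0, 1.0, 10, 1.0, 1.0, 10) == pytest.approx(1.0)
    with pytest.raises(UndefinedMeasureError):
        cohens_d_from_moments(1.0, 0.0, 5, 0.0, 0.0, 5)
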