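import numpy as np
import pytest

from fuzzylump import (
    DegenerateClusterError,
    LumpedChain,
    Partition,
    build_chain,
    indicator,
    lift,
    load_network,
    lump_fuzzy,
    lump_hard,
    lumped_stationary,
    objective,
    optimal_lumped,
    unconstrained_optimal_phat,
    validate_membership,
)


def brute_force_lump(P, mu, rho):
    """Element-wise double-sum evaluation of the aggregation formula."""
    N, K = rho.shape
    mu_hat = np.array([sum(mu[x] * rho[x, k] for x in range(N)) for k in range(K)])
    p_hat = np.zeros((K, K))
    for k in range(K):
        for l in range(K):
            p_hat[k, l] = (
                sum(
                    mu[x] * rho[x, k] * P[x, y] * rho[y, l]
                    for x in range(N)
                    for y in range(N)
                )
                / mu_hat[k]
            )
    return p_hat, mu_hat


def brute_force_objective(P, mu, rho, p_hat, mu_hat):
    N, K = rho.shape
    J = 0.0
    for x in range(N):
        for y in range(N):
            pt = sum(
                rho[x, k] * p_hat[k, l] * mu[y] * rho[y, l] / mu_hat[l]
                for k in range(K)
                for l in range(K)
            )
            J += mu[x] / mu[y] * (P[x, y] - pt) ** 2
    return J


class TestLumpedStationary:
    def test_triangle_hard_split(self, triangle_chain):
        rho = indicator(Partition(assignment=[0, 1, 1], K=2))
        mu_hat = lumped_stationary(rho, triangle_chain.mu)
        assert np.allclose(mu_hat, [1 / 3, 2 / 3])

    def test_uniform_membership_gives_uniform(self, triangle_chain):
        rho = np.full((3, 3), 1 / 3)
        assert np.allclose(lumped_stationary(rho, triangle_chain.mu), 1 / 3)

    def test_sums_to_one(self, random_chain_factory, random_membership_factory):
        chain = random_chain_factory(6, 0)
        rho = random_membership_factory(6, 3, 1)
        assert lumped_stationary(rho, chain.mu).sum() == pytest.approx(1.0)

    def test_zero_mass_cluster_raises(self, triangle_chain):
        rho = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateClusterError, match="cluster 1"):
            lumped_stationary(rho, triangle_chain.mu)


class TestLumpHard:
    def test_identity_partition_returns_p(self, triangle_chain):
        part = Partition(assignment=[0, 1, 2], K=3)
        lumped = lump_hard(triangle_chain, part)
        assert np.allclose(lumped.p_hat, triangle_chain.P, atol=1e-15)

    def test_triangle_two_split_against_brute_force(self, triangle_chain):
        part = Partition(assignment=[0, 1, 1], K=2)
        lumped = lump_hard(triangle_chain, part)
        expected, _ = brute_force_lump(
            triangle_chain.P, triangle_chain.mu, indicator(part)
        )
        assert np.allclose(lumped.p_hat, expected, atol=1e-14)
        # frozen brute-force values for the 3-cycle
        assert np.allclose(lumped.p_hat, [[0.0, 1.0], [0.5, 0.5]])

    def test_single_cluster_total_mass(self, triangle_chain):
        lumped = lump_hard(triangle_chain, Partition(assignment=[0, 0, 0], K=1))
        assert np.allclose(lumped.p_hat, [[1.0]])


class TestLumpFuzzy:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_indicator_reduces_to_hard(self, random_chain_factory, seed):
        chain = random_chain_factory(7, seed)
        rng = np.random.default_rng(seed)
        assign = rng.integers(0, 3, 7)
        assign[:3] = [0, 1, 2]
        part = Partition(assignment=assign, K=3)
        hard = lump_hard(chain, part)
        fuzzy = lump_fuzzy(chain, indicator(part))
        assert np.allclose(hard.p_hat, fuzzy.p_hat, atol=1e-12)

    def test_uniform_membership_gives_uniform_phat(self, random_chain_factory):
        chain = random_chain_factory(6, 5)
        rho = np.full((6, 4), 0.25)
        lumped = lump_fuzzy(chain, rho)
        assert np.allclose(lumped.p_hat, 0.25, atol=1e-14)

    def test_rows_stochastic_and_detailed_balance(
        self, random_chain_factory, random_membership_factory
    ):
        chain = random_chain_factory(6, 7)
        rho = random_membership_factory(6, 3, 7)
        lumped = lump_fuzzy(chain, rho)
        assert np.allclose(lumped.p_hat.sum(axis=1), 1.0, atol=1e-12)
        assert lumped.detailed_balance_violation() <= 1e-10

    def test_matches_brute_force(self, random_chain_factory, random_membership_factory):
        chain = random_chain_factory(5, 11)
        rho = random_membership_factory(5, 2, 11)
        lumped = lump_fuzzy(chain, rho)
        p_hat, mu_hat = brute_force_lump(chain.P, chain.mu, rho)
        assert np.allclose(lumped.p_hat, p_hat, atol=1e-12)
        assert np.allclose(lumped.mu_hat, mu_hat, atol=1e-12)


class TestLift:
    def test_identity_membership_lifts_to_p(self, random_chain_factory):
        chain = random_chain_factory(6, 0)
        rho = np.eye(6)
        lumped = lump_fuzzy(chain, rho)
        assert np.allclose(lift(lumped, rho, chain.mu), chain.P, atol=1e-14)

    def test_single_cluster_lift_is_rank_one(self, random_chain_factory):
        chain = random_chain_factory(5, 1)
        rho = np.ones((5, 1))
        lumped = lump_fuzzy(chain, rho)
        lifted = lift(lumped, rho, chain.mu)
        assert np.allclose(lifted, np.tile(chain.mu, (5, 1)), atol=1e-14)

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_lifted_rows_sum_to_one(
        self, random_chain_factory, random_membership_factory, seed
    ):
        chain = random_chain_factory(8, seed)
        rho = random_membership_factory(8, 3, seed)
        lifted = lift(lump_fuzzy(chain, rho), rho, chain.mu)
        assert np.allclose(lifted.sum(axis=1), 1.0, atol=1e-12)

    def test_lump_lift_consistency_for_hard_membership(self, karate_chain):
        from fuzzylump import MarkovChain, karate_factions

        rho = indicator(karate_factions())
        lumped = lump_fuzzy(karate_chain, rho)
        lifted = MarkovChain(
            P=lift(lumped, rho, karate_chain.mu), mu=karate_chain.mu
        )
        relumped = lump_fuzzy(lifted, rho)
        assert np.allclose(relumped.p_hat, lumped.p_hat, atol=1e-12)


class TestObjective:
    def test_perfect_reconstruction_is_zero(self, random_chain_factory):
        chain = random_chain_factory(6, 2)
        rho = np.eye(6)
        lumped = lump_fuzzy(chain, rho)
        assert objective(chain, rho, lumped) <= 1e-25

    def test_matches_brute_force_double_sum(
        self, random_chain_factory, random_membership_factory
    ):
        chain = random_chain_factory(6, 13)
        rho = random_membership_factory(6, 3, 13)
        lumped = lump_fuzzy(chain, rho)
        J = objective(chain, rho, lumped)
        assert J >= 0.0
        expected = brute_force_objective(
            chain.P, chain.mu, rho, lumped.p_hat, lumped.mu_hat
        )
        assert J == pytest.approx(expected, rel=1e-10)

    def test_invariant_under_label_permutation(
        self, random_chain_factory, random_membership_factory
    ):
        chain = random_chain_factory(7, 17)
        rho = random_membership_factory(7, 3, 17)
        lumped = lump_fuzzy(chain, rho)
        perm = [2, 0, 1]
        lumped_p = LumpedChain(
            p_hat=lumped.p_hat[np.ix_(perm, perm)], mu_hat=lumped.mu_hat[perm]
        )
        assert objective(chain, rho[:, perm], lumped_p) == pytest.approx(
            objective(chain, rho, lumped)
        )

    def test_frobenius_switch(self, random_chain_factory, random_membership_factory):
        chain = random_chain_factory(5, 19)
        rho = random_membership_factory(5, 2, 19)
        lumped = lump_fuzzy(chain, rho)
        J_frob = objective(chain, rho, lumped, weighting="frobenius")
        E = chain.P - lift(lumped, rho, chain.mu)
        assert J_frob == pytest.approx(np.sum(E**2))


class TestOptimalLumped:
    def test_hard_membership_equals_lump_hard(self, karate_chain):
        from fuzzylump import karate_factions

        part = karate_factions()
        assert np.allclose(
            optimal_lumped(karate_chain, indicator(part)).p_hat,
            lump_hard(karate_chain, part).p_hat,
        )

    def test_identity_membership_recovers_p_with_zero_objective(
        self, random_chain_factory
    ):
        chain = random_chain_factory(5, 23)
        rho = np.eye(5)
        lumped = optimal_lumped(chain, rho)
        assert np.allclose(lumped.p_hat, chain.P, atol=1e-14)
        assert objective(chain, rho, lumped) <= 1e-25

    @pytest.mark.parametrize("hard", [True, False])
    def test_minimizer_beats_random_stochastic_probes(
        self, random_chain_factory, random_membership_factory, hard
    ):
        """For hard memberships the aggregation formula is the exact
        minimizer; for fuzzy ones the minimizer is the closed-form solve
        (the aggregation formula is only a stochastic surrogate there)."""
        chain = random_chain_factory(6, 29)
        if hard:
            rho = indicator(Partition(assignment=[0, 0, 1, 1, 2, 2], K=3))
            lumped = optimal_lumped(chain, rho)
        else:
            rho = random_membership_factory(6, 3, 29)
            agg = optimal_lumped(chain, rho)
            lumped = LumpedChain(
                p_hat=unconstrained_optimal_phat(chain, rho), mu_hat=agg.mu_hat
            )
        J_star = objective(chain, rho, lumped)
        rng = np.random.default_rng(31)
        for _ in range(20):
            Q = rng.dirichlet(np.ones(3), size=3)
            probe = LumpedChain(p_hat=Q, mu_hat=lumped.mu_hat)
            assert J_star <= objective(chain, rho, probe) + 1e-12

    def test_unconstrained_minimizer_dominates_on_hard(self, random_chain_factory):
        """On indicator memberships the closed form equals the aggregation."""
        chain = random_chain_factory(6, 37)
        rho = indicator(Partition(assignment=[0, 1, 1, 0, 1, 0], K=2))
        assert np.allclose(
            unconstrained_optimal_phat(chain, rho),
            optimal_lumped(chain, rho).p_hat,
            atol=1e-10,
        )

    def test_unconstrained_minimizer_lower_bound(
        self, random_chain_factory, random_membership_factory
    ):
        """The exact closed form never exceeds the aggregation's objective."""
        chain = random_chain_factory(6, 41)
        rho = random_membership_factory(6, 2, 41)
        agg = optimal_lumped(chain, rho)
        exact = LumpedChain(
            p_hat=unconstrained_optimal_phat(chain, rho), mu_hat=agg.mu_hat
        )
        assert objective(chain, rho, exact) <= objective(chain, rho, agg) + 1e-12


class TestSplittingMonotonicity:
    def test_minimal_objective_non_increasing_under_cluster_split(self):
        net = load_network(
            "1 2\n1 3\n2 3\n3 4\n4 5\n4 6\n5 6", weighted=False
        )  # two triangles joined by a bridge
        chain = build_chain(net)
        coarse = Partition(assignment=[0, 0, 0, 1, 1, 1], K=2)
        J_coarse = objective(
            chain, indicator(coarse), optimal_lumped(chain, indicator(coarse))
        )
        # split cluster 0 in every possible nontrivial way
        for split in ([0, 2, 2, 1, 1, 1], [2, 0, 2, 1, 1, 1], [2, 2, 0, 1, 1, 1]):
            fine = Partition(assignment=split, K=3)
            J_fine = objective(
                chain, indicator(fine), optimal_lumped(chain, indicator(fine))
            )
            assert J_fine <= J_coarse + 1e-12


class TestMembershipValidation:
    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError, match="nonnegative"):
            validate_membership(np.array([[1.2, -0.2]]))
        with pytest.raises(ValueError, match="sum to 1"):
            validate_membership(np.array([[0.5, 0.4]]))

    def test_aggregated_weights_recoverable(self, random_chain_factory):
        """mu_hat[k] p_hat[k,l] recovers the symmetric aggregated flux."""
        chain = random_chain_factory(6, 43)
        part = Partition(assignment=[0, 0, 1, 1, 1, 0], K=2)
        lumped = lump_hard(chain, part)
        w_hat = lumped.mu_hat[:, None] * lumped.p_hat
        assert np.allclose(w_hat, w_hat.T, atol=1e-12)
        assert w_hat.sum() == pytest.approx(1.0)
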