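"""Model densities, the propensity layer, and prior-scaling properties."""

import numpy as np
import pytest

from behavstate import (
    Assignments,
    BinnedDataset,
    Hyperpriors,
    RegressionState,
    StateParams,
    animal_log_likelihood,
    joint_log_density,
    propensity,
    softmax,
    state_log_likelihood,
)


class TestStateLogLikelihood:
    def test_single_behavior_picks_level_probability(self):
        theta = StateParams(
            theta=np.array([[[0.2, 0.3, 0.5]]]), n_levels=np.array([3])
        )
        assert state_log_likelihood([3], 0, theta) == pytest.approx(np.log(0.5))

    def test_uniform_states_give_b_log_third(self):
        B = 4
        theta = StateParams(
            theta=np.full((2, B, 3), 1 / 3), n_levels=np.full(B, 3)
        )
        assert state_log_likelihood([1, 2, 3, 1], 1, theta) == pytest.approx(
            B * np.log(1 / 3)
        )

    def test_two_behavior_hand_product(self):
        theta = np.zeros((1, 2, 2))
        theta[0, 0] = [0.1, 0.9]
        theta[0, 1] = [0.25, 0.75]
        sp = StateParams(theta=theta, n_levels=np.array([2, 2]))
        assert state_log_likelihood([2, 1], 0, sp) == pytest.approx(
            np.log(0.9 * 0.25)
        )

    def test_out_of_range_level_raises(self):
        sp = StateParams(theta=np.array([[[0.5, 0.5]]]), n_levels=np.array([2]))
        with pytest.raises(ValueError):
            state_log_likelihood([3], 0, sp)


class TestAnimalLogLikelihood:
    def test_empty_product_is_zero(self, uniform_states):
        assert animal_log_likelihood(np.empty((0, 2)), [], uniform_states) == 0.0

    def test_matches_per_row_sum(self, uniform_states, rng):
        rows = np.column_stack(
            [rng.integers(1, 4, size=3), rng.integers(1, 3, size=3)]
        )
        z = rng.integers(0, 2, size=3)
        expected = sum(
            state_log_likelihood(rows[f], z[f], uniform_states) for f in range(3)
        )
        assert animal_log_likelihood(rows, z, uniform_states) == pytest.approx(
            expected
        )


class TestSoftmaxAndPropensity:
    def test_zero_propensities_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(5)), np.full(5, 0.2))

    def test_log_two_example(self):
        np.testing.assert_allclose(
            softmax(np.array([np.log(2), 0.0])), [2 / 3, 1 / 3]
        )

    def test_shift_invariance_and_overflow_safety(self, rng):
        eta = rng.normal(size=(4, 3))
        np.testing.assert_allclose(softmax(eta), softmax(eta + 1000.0))

    def test_propensity_composition(self, rng):
        N, P, K = 5, 2, 3
        alpha = rng.normal(size=K)
        X = rng.normal(size=(N, P))
        beta = rng.normal(size=(P, K))
        u = rng.normal(size=(N, K))
        eps = rng.normal(size=(N, K))
        eta = propensity(alpha, X, beta, u, eps)
        # elementwise oracle
        for i in range(N):
            for k in range(K):
                assert eta[i, k] == pytest.approx(
                    alpha[k] + X[i] @ beta[:, k] + u[i, k] + eps[i, k]
                )

    def test_propensity_reduces_to_alpha(self):
        eta = propensity(np.array([1.0, -1.0]), None, np.empty((0, 2)), None, np.zeros((3, 2)))
        np.testing.assert_allclose(eta, np.tile([1.0, -1.0], (3, 1)))

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            propensity(np.zeros(2), rng.normal(size=(3, 2)), rng.normal(size=(3, 2)), None, np.zeros((3, 2)))


class TestJointLogDensity:
    def _setup(self, n_obs):
        data = BinnedDataset(
            levels=np.ones((n_obs, 1), dtype=np.int64),
            animal_index=np.zeros(n_obs, dtype=np.int64),
            animal_ids=["a"],
            behavior_names=["x"],
            n_levels=np.array([2]),
        )
        theta = StateParams(theta=np.array([[[0.7, 0.3]], [[0.4, 0.6]]]), n_levels=np.array([2]))
        reg = RegressionState(
            alpha=np.array([0.3, -0.3]),
            beta=np.empty((0, 2)),
            u=None,
            eps=np.array([[0.1, -0.2]]),
            sigma2=np.array([1.0, 1.0]),
            tau=1.0,
            gamma=None,
        )
        assign = Assignments(
            z=np.zeros(n_obs, dtype=np.int64),
            n_animals=1,
            n_states=2,
            animal_index=np.zeros(n_obs, dtype=np.int64),
        )
        return data, theta, reg, assign

    def test_one_observation_adds_its_own_contribution(self):
        data1, theta, reg, assign1 = self._setup(1)
        data2, _, _, assign2 = self._setup(2)
        d1 = joint_log_density(data1, assign1, theta, reg)
        d2 = joint_log_density(data2, assign2, theta, reg)
        eta = reg.eta(None)
        logpi = eta - np.log(np.exp(eta).sum())
        expected_delta = np.log(0.7) + logpi[0, 0]
        assert d2 - d1 == pytest.approx(expected_delta)

    def test_tiny_instance_brute_force(self):
        """Direct summation of every density term on a 1-animal instance."""
        from scipy import stats

        data, theta, reg, assign = self._setup(2)
        hyper = Hyperpriors()
        got = joint_log_density(data, assign, theta, reg, hyper=hyper)
        eta = reg.eta(None)
        pi = np.exp(eta) / np.exp(eta).sum()
        expected = (
            2 * np.log(0.7)  # two obs at level 1 of state 1
            + 2 * np.log(pi[0, 0])
            + stats.norm.logpdf(reg.alpha, 0, np.sqrt(reg.tau * reg.sigma2)).sum()
            + stats.norm.logpdf(reg.eps, 0, 1.0).sum()
            + stats.invgamma.logpdf(reg.sigma2, 0.005, scale=0.0005).sum()
            + stats.invgamma.logpdf(reg.tau, 0.005, scale=0.0005)
            # Dirichlet(1) over L=2 levels: density Gamma(2)/Gamma(1)^2 = 1
            + 0.0
        )
        assert got == pytest.approx(expected, abs=1e-8)


class TestPriorScaling:
    """Prior-predictive reproduction of the random-effect variance structure."""

    def test_variance_scaling_of_random_effects(self, rng, sib_pedigree):
        from behavstate import kinship_matrix, relatedness_matrix

        A = relatedness_matrix(kinship_matrix(sib_pedigree)).A
        N = A.shape[0]
        sigma2, tau, gamma = 0.7, 2.0, 3.0
        L = np.linalg.cholesky(A + 1e-10 * np.eye(N))
        reps = 30_000
        alpha = rng.normal(0, np.sqrt(tau * sigma2), size=reps)
        eps = rng.normal(0, np.sqrt(sigma2), size=reps)
        u = np.sqrt(gamma * sigma2) * (L @ rng.normal(size=(N, reps)))
        assert np.var(alpha) == pytest.approx(tau * sigma2, rel=0.05)
        assert np.var(eps) == pytest.approx(sigma2, rel=0.05)
        # cov(u) proportional to A: check a founder pair vs a sib pair
        cov_sibs = np.cov(u[4], u[5])[0, 1]
        assert cov_sibs == pytest.approx(gamma * sigma2 * A[4, 5], rel=0.1)
        assert np.var(u[0]) == pytest.approx(gamma * sigma2 * A[0, 0], rel=0.05)

    def test_heritability_prior_mass_near_both_tails(self, rng):
        hyper = Hyperpriors()
        g = 1.0 / rng.gamma(hyper.gamma_shape, 1.0 / hyper.gamma_rate, size=100_000)
        h = g / (1.0 + g)
        assert (h <= 0.1).mean() > 0.10
        assert (h >= 0.9).mean() > 0.10


def test_phenotype_rows_sum_to_one(rng):
    from behavstate import Phenotype

    ph = Phenotype(eta=rng.normal(size=(10, 4)))
    np.testing.assert_allclose(ph.pi.sum(axis=1), 1.0)
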