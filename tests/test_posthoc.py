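"""Post-sampling analyses: prediction, matching, pseudo-h2, repeatability."""

import numpy as np
import pytest

from behavstate import (
    CovariateProfile,
    PosteriorSamples,
    StateParams,
    baseline_relative_coefficients,
    greedy_state_match,
    phenotype_recovery,
    predict_phenotype,
    pseudo_h2,
    repeatability,
    simulate_states,
    softmax,
)


def _make_samples(alpha, beta, u=None, eps=None, names=None):
    alpha = np.asarray(alpha, dtype=float)
    S, K = alpha.shape
    beta = np.asarray(beta, dtype=float)
    P = beta.shape[1]
    N = 1 if eps is None else np.asarray(eps).shape[1]
    eps = np.zeros((S, N, K)) if eps is None else np.asarray(eps, dtype=float)
    theta = np.full((S, K, 1, 2), 0.5)
    return PosteriorSamples(
        theta=theta,
        alpha=alpha,
        beta=beta,
        u=None if u is None else np.asarray(u, dtype=float),
        eps=eps,
        sigma2=np.ones((S, K)),
        tau=np.ones(S),
        gamma=None if u is None else np.ones((S, K)),
        z=np.zeros((S, 1), dtype=np.int32),
        chain=np.zeros(S, dtype=np.int32),
        iteration=np.arange(S),
        n_levels=np.array([2]),
        animal_ids=[f"a{i}" for i in range(N)],
        covariate_names=names or [f"x{j}" for j in range(P)],
    )


class TestPredictPhenotype:
    def test_draws_sum_to_one(self, rng):
        s = _make_samples(rng.normal(size=(20, 3)), rng.normal(size=(20, 2, 3)))
        pred = predict_phenotype(CovariateProfile({"x0": 1.0}), s)
        np.testing.assert_allclose(pred["draws"].sum(axis=1), 1.0)

    def test_zero_beta_profile_independent(self, rng):
        s = _make_samples(rng.normal(size=(10, 3)), np.zeros((10, 2, 3)))
        p1 = predict_phenotype(CovariateProfile({"x0": -2.0}), s)
        p2 = predict_phenotype(CovariateProfile({"x1": 5.0}), s)
        np.testing.assert_allclose(p1["draws"], p2["draws"])

    def test_single_draw_hand_softmax(self):
        alpha = np.array([[0.5, -0.5]])
        beta = np.array([[[1.0, 0.0]]])  # (S=1, P=1, K=2)
        s = _make_samples(alpha, beta)
        pred = predict_phenotype(CovariateProfile({"x0": 2.0}), s)
        np.testing.assert_allclose(
            pred["draws"][0], softmax(np.array([0.5 + 2.0, -0.5]))
        )

    def test_unknown_covariate_rejected(self, rng):
        s = _make_samples(rng.normal(size=(5, 2)), rng.normal(size=(5, 1, 2)))
        with pytest.raises(KeyError):
            predict_phenotype(CovariateProfile({"age": 1.0}), s)


class TestBaselineRelativeCoefficients:
    def test_two_state_hand_subtraction(self):
        alpha = np.array([[1.0, 0.25], [2.0, 0.5]])
        beta = np.array([[[0.3, 0.1]], [[0.4, 0.2]]])
        s = _make_samples(alpha, beta)
        df = baseline_relative_coefficients(s, baseline=0)
        inter = df[(df.state == 1) & (df.term == "(intercept)")]["mean"].item()
        slope = df[(df.state == 1) & (df.term == "x0")]["mean"].item()
        assert inter == pytest.approx(np.mean([0.25 - 1.0, 0.5 - 2.0]))
        assert slope == pytest.approx(np.mean([0.1 - 0.3, 0.2 - 0.4]))

    def test_common_shift_invariance(self, rng):
        alpha = rng.normal(size=(8, 3))
        beta = rng.normal(size=(8, 2, 3))
        s1 = _make_samples(alpha, beta)
        s2 = _make_samples(alpha + 5.0, beta + rng.normal(size=(8, 2, 1)))
        d1 = baseline_relative_coefficients(s1, 1)
        d2 = baseline_relative_coefficients(s2, 1)
        np.testing.assert_allclose(
            d1[d1.term == "(intercept)"]["mean"], d2[d2.term == "(intercept)"]["mean"]
        )
        np.testing.assert_allclose(d1["mean"], d2["mean"])


class TestPseudoH2:
    def _samples(self, u, eps, alpha=None, X=None, beta=None):
        u = np.asarray(u, dtype=float)[None]  # single draw
        eps = np.asarray(eps, dtype=float)[None]
        N, K = u.shape[1:]
        alpha = np.zeros((1, K)) if alpha is None else np.asarray(alpha)[None]
        beta = np.empty((1, 0, K)) if beta is None else np.asarray(beta)[None]
        return _make_samples(alpha[0][None], beta, u=u, eps=eps)

    def test_eps_zero_gives_one(self, rng):
        N, K = 12, 3
        u = rng.normal(size=(N, K))
        s = self._samples(u, np.zeros((N, K)))
        res = pseudo_h2(s, None)
        np.testing.assert_allclose(res.draws[0], 1.0, atol=1e-12)

    def test_u_zero_gives_zero(self, rng):
        N, K = 12, 3
        s = self._samples(np.zeros((N, K)), rng.normal(size=(N, K)))
        res = pseudo_h2(s, None)
        np.testing.assert_allclose(res.draws[0], 0.0, atol=1e-12)

    def test_counterproductive_genetics_goes_negative(self):
        """A draw where u anticorrelates with the residual structure makes
        the genetic prediction worse and pseudo-h2 negative."""
        N, K = 6, 2
        rng = np.random.default_rng(0)
        u = np.zeros((N, K))
        u[:, 0] = np.linspace(-1, 1, N)
        u[:, 1] = -u[:, 0]
        # eps nearly cancels u, so the full phenotype sits close to the
        # covariate-only prediction while the genetic prediction swings wide
        eps = -u + 0.05 * rng.normal(size=(N, K))
        res = pseudo_h2(self._samples(u, eps), None)
        assert (res.draws[0] < 0).all()

    def test_requires_genetic_component(self, rng):
        s = _make_samples(rng.normal(size=(3, 2)), rng.normal(size=(3, 1, 2)))
        with pytest.raises(ValueError, match="genetic"):
            pseudo_h2(s, None)

    def test_shift_invariance(self, rng):
        N, K = 10, 3
        u = rng.normal(size=(N, K))
        eps = rng.normal(size=(N, K))
        r1 = pseudo_h2(self._samples(u, eps), None)
        r2 = pseudo_h2(self._samples(u, eps, alpha=np.full(K, 7.0)), None)
        # common additive shift of all propensities changes nothing... the
        # shift enters both pi and pi-hat identically
        np.testing.assert_allclose(r1.draws, r2.draws, atol=1e-10)


class TestGreedyStateMatch:
    def test_self_match_is_identity(self, rng):
        sp = simulate_states(4, 6, rng=rng)
        m = greedy_state_match(sp, sp)
        assert m.fitted_to_ref == {k: k for k in range(4)}
        assert all(c == pytest.approx(1.0) for c in m.correlations.values())

    def test_permutation_recovered(self, rng):
        sp = simulate_states(5, 6, rng=rng)
        perm = rng.permutation(5)
        permuted = StateParams(theta=sp.theta[perm], n_levels=sp.n_levels)
        m = greedy_state_match(permuted, sp)
        for kf, kr in m.fitted_to_ref.items():
            assert kr == perm[kf]
            assert m.correlations[kf] == pytest.approx(1.0)

    def test_noise_state_matches_last_without_disturbing_others(self, rng):
        sp = simulate_states(3, 8, rng=rng)
        noise = simulate_states(1, 8, rng=rng)
        fitted = StateParams(
            theta=np.concatenate([sp.theta, noise.theta]), n_levels=sp.n_levels
        )
        m = greedy_state_match(fitted, sp)
        # three real states match themselves perfectly; the noise state is
        # left over (no reference remains)
        for k in range(3):
            assert m.fitted_to_ref[k] == k
            assert m.correlations[k] == pytest.approx(1.0)
        assert m.unmatched_fitted == [3]


class TestPhenotypeRecovery:
    def test_exact_recovery_gives_unit_correlations(self, rng):
        sp = simulate_states(4, 5, rng=rng)
        pi = rng.dirichlet(np.ones(4), size=10)
        m = greedy_state_match(sp, sp)
        r = phenotype_recovery(m, pi, pi)
        np.testing.assert_allclose(r, 1.0)

    def test_permuted_recovery_is_undone_by_matching(self, rng):
        sp = simulate_states(4, 5, rng=rng)
        perm = rng.permutation(4)
        fitted = StateParams(theta=sp.theta[perm], n_levels=sp.n_levels)
        pi = rng.dirichlet(np.ones(4), size=10)
        m = greedy_state_match(fitted, sp)
        r = phenotype_recovery(m, pi, pi[:, perm])
        np.testing.assert_allclose(r, 1.0)

    def test_hand_pearson(self):
        m_obj = greedy_state_match(
            simulate_states(3, 4, rng=np.random.default_rng(0)),
            simulate_states(3, 4, rng=np.random.default_rng(0)),
        )
        true_pi = np.array([[0.5, 0.3, 0.2]])
        fit_pi = np.array([[0.4, 0.4, 0.2]])
        r = phenotype_recovery(m_obj, true_pi, fit_pi)
        expected = np.corrcoef([0.5, 0.3, 0.2], [0.4, 0.4, 0.2])[0, 1]
        assert r[0] == pytest.approx(expected)


class TestRepeatability:
    def test_identical_years_give_one(self, rng):
        pi = rng.dirichlet(np.ones(3), size=8)
        np.testing.assert_allclose(repeatability(pi, pi), 1.0)

    def test_shuffled_second_year_near_zero(self, rng):
        pi = rng.dirichlet(np.ones(4), size=3000)
        shuffled = pi[rng.permutation(len(pi))]
        r = repeatability(pi, shuffled)
        np.testing.assert_allclose(r, 0.0, atol=0.06)

    def test_hand_pearson_five_animals(self):
        p1 = np.array([[0.2, 0.8], [0.4, 0.6], [0.5, 0.5], [0.7, 0.3], [0.9, 0.1]])
        p2 = np.array([[0.3, 0.7], [0.35, 0.65], [0.6, 0.4], [0.6, 0.4], [0.8, 0.2]])
        r = repeatability(p1, p2)
        for k in range(2):
            assert r[k] == pytest.approx(np.corrcoef(p1[:, k], p2[:, k])[0, 1])

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError, match="3 animals"):
            repeatability(np.ones((2, 2)) / 2, np.ones((2, 2)) / 2)
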