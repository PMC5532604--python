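"""Partially-collapsed Gibbs sampler for the behavioral-state model.

Update cycle per iteration:

1. ``z`` — each focal observation's state from its categorical full
   conditional (prior pi_i times data likelihood), in log space;
2. ``theta`` — conjugate Dirichlet updates per state and behavior;
3. regression block — for each state k, the multinomial-logit layer is
   reduced to a Gaussian layer by Pólya-Gamma augmentation in one-vs-rest
   form: with the other states' propensities held fixed in an offset
   ``C_i = log sum_{k' != k} exp(eta_{i,k'})``, the conditional of
   ``psi_i = eta_{i,k} - C_i`` is a binomial logit with n_{i,k} successes of
   n_i trials, so ``omega_i ~ PG(n_i, psi_i)`` makes
   ``(alpha_k, beta_k, u_{.,k}, eps_{.,k})`` jointly Gaussian.  The whole
   block is drawn in one solve (the partial collapse), which mixes far
   better than component-wise updates;
4. variance components — conjugate inverse-gamma draws for sigma2_k, tau
   and gamma_k, with sigma2_k pooling the eps, alpha and u quadratic forms
   through the shared-scale parameterization.

The sampler also exposes a successive-conditional ("joint distribution
test") simulator used to validate its correctness against the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

from .data import BinnedDataset
from .initialization import initial_assignments
from .model import (
    Assignments,
    Hyperpriors,
    RegressionState,
    StateParams,
    loglik_matrix,
    softmax,
)
from .pg import polya_gamma

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "sample_assignments",
    "sample_state_params",
    "sample_regression_block",
    "sample_variances",
    "run_chain",
    "fit_model",
    "geweke_joint_chain",
]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings.  Defaults mirror a long production run (two chains of
    100,000 iterations thinned to 1,000 kept draws each, the first 100 kept
    draws discarded as burn-in); tests and examples pass much smaller
    values."""

    n_iterations: int = 100_000
    thin_to: int = 1000
    burn_in_kept: int = 100
    n_chains: int = 2
    seed: int = 0
    jitter: float = 1e-8

    def __post_init__(self):
        if self.n_iterations < self.thin_to:
            raise ValueError("n_iterations must be >= thin_to")
        if not 0 <= self.burn_in_kept < self.thin_to:
            raise ValueError("burn_in_kept must be < thin_to")

    def kept_iterations(self) -> np.ndarray:
        """0-based iteration indices of the thin_to evenly spaced kept draws."""
        grid = np.floor(
            (np.arange(1, self.thin_to + 1) * self.n_iterations) / self.thin_to
        ).astype(int) - 1
        return grid


@dataclass
class PosteriorSamples:
    """Thinned posterior draws of every unknown, stacked across chains."""

    theta: np.ndarray  # (S, K, B, Lmax)
    alpha: np.ndarray  # (S, K)
    beta: np.ndarray  # (S, P, K)
    u: np.ndarray | None  # (S, N, K)
    eps: np.ndarray  # (S, N, K)
    sigma2: np.ndarray  # (S, K)
    tau: np.ndarray  # (S,)
    gamma: np.ndarray | None  # (S, K)
    z: np.ndarray  # (S, N_obs) int
    chain: np.ndarray  # (S,)
    iteration: np.ndarray  # (S,)
    n_levels: np.ndarray
    animal_ids: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @property
    def n_states(self) -> int:
        return self.theta.shape[1]

    def eta_draw(self, s: int, X: np.ndarray | None) -> np.ndarray:
        """Rebuild the propensity matrix of draw s."""
        eta = self.alpha[s][None, :] + self.eps[s]
        if X is not None and self.beta.shape[1]:
            eta = eta + X @ self.beta[s]
        if self.u is not None:
            eta = eta + self.u[s]
        return eta

    def pi_draws(self, X: np.ndarray | None) -> np.ndarray:
        """(S, N, K) posterior draws of the phenotypes pi."""
        return np.stack(
            [softmax(self.eta_draw(s, X), axis=1) for s in range(self.n_draws)]
        )

    def mean_theta(self) -> StateParams:
        m = self.theta.mean(axis=0)
        m = m / np.clip(m.sum(axis=2, keepdims=True), 1e-300, None)
        # re-zero padding lost to normalization noise
        pad = np.arange(m.shape[2])[None, :] >= self.n_levels[:, None]
        m[:, pad] = 0.0
        m = m / m.sum(axis=2, keepdims=True)
        return StateParams(theta=m, n_levels=self.n_levels)


def sample_assignments(
    data: BinnedDataset,
    theta: StateParams,
    pi: np.ndarray,
    rng: np.random.Generator,
    loglik: np.ndarray | None = None,
) -> np.ndarray:
    """Draw z_{i,f} ~ Categorical with mass prop. to pi_{i,k} p(y_f | theta_k)."""
    if loglik is None:
        loglik = loglik_matrix(data, theta)  # (K, N_obs)
    with np.errstate(divide="ignore"):
        logpi = np.log(np.clip(pi, 0.0, None))
        logpi[pi == 0] = -np.inf
    scores = logpi[data.animal_index] + loglik.T  # (N_obs, K)
    if np.any(np.all(np.isinf(scores) & (scores < 0), axis=1)):
        raise ValueError("an observation has zero posterior mass in every state")
    return np.argmax(scores + rng.gumbel(size=scores.shape), axis=1)


def sample_state_params(
    data: BinnedDataset,
    z: np.ndarray,
    K: int,
    rng: np.random.Generator,
    conc: float = 1.0,
) -> StateParams:
    """Conjugate Dirichlet(conc + level counts) draw of every theta table."""
    B = data.n_behaviors
    Lmax = int(data.n_levels.max())
    counts = np.zeros((K, B, Lmax))
    lev = data.levels - 1
    for b in range(B):
        flat = z * Lmax + lev[:, b]
        counts[:, b, :] = np.bincount(flat, minlength=K * Lmax).reshape(K, Lmax)
    pad = np.arange(Lmax)[None, :] >= data.n_levels[:, None]
    shape = counts + conc
    shape[:, pad] = 0.0  # gamma(0) == 0: padding stays exactly zero
    g = rng.gamma(np.clip(shape, 0.0, None))
    g[:, pad] = 0.0
    theta = g / g.sum(axis=2, keepdims=True)
    return StateParams(theta=theta, n_levels=data.n_levels)


def _prepare_A_inverse(A: np.ndarray | None, jitter: float) -> np.ndarray | None:
    if A is None:
        return None
    n = A.shape[0]
    try:
        c, low = linalg.cho_factor(A + jitter * np.eye(n), lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(
            "relatedness matrix is not positive definite; increase the jitter"
        ) from err
    return linalg.cho_solve((c, low), np.eye(n))


def sample_regression_block(
    counts: np.ndarray,
    totals: np.ndarray,
    X: np.ndarray | None,
    Ainv: np.ndarray | None,
    reg: RegressionState,
    hyper: Hyperpriors,
    rng: np.random.Generator,
    eta: np.ndarray | None = None,
) -> tuple[RegressionState, np.ndarray]:
    """One sweep of per-state joint Gaussian draws of (alpha_k, beta_k, u_k, eps_k).

    ``counts`` is the (N, K) matrix n_{i,k} and ``totals`` the per-animal
    n_i.  Returns the updated regression state and propensity matrix.
    """
    N, K = counts.shape
    has_X = X is not None and X.shape[1] > 0
    P = X.shape[1] if has_X else 0
    has_gen = Ainv is not None
    if eta is None:
        eta = reg.eta(X if has_X else None)
    eta = eta.copy()

    alpha = reg.alpha.copy()
    beta = reg.beta.copy()
    u = reg.u.copy() if reg.u is not None else None
    eps = reg.eps.copy()

    iu = slice(1 + P, 1 + P + N) if has_gen else None
    ie = slice(1 + P + (N if has_gen else 0), None)
    d = 1 + P + (2 * N if has_gen else N)

    for k in range(K):
        if K == 1:
            # a single state has pi = 1 regardless of eta: the likelihood
            # carries no information and the conditional is the prior
            C = np.zeros(N)
            omega = np.full(N, 1e-12)
            resid = np.zeros(N)
        else:
            others = np.delete(np.arange(K), k)
            C = logsumexp(eta[:, others], axis=1)
            psi = eta[:, k] - C
            omega = polya_gamma(totals, psi, rng)
            omega = np.clip(omega, 1e-12, None)  # guard animals with n_i = 0
            kappa = counts[:, k] - totals / 2.0
            resid = kappa + omega * C  # = Omega * pseudo-response

        Q = np.zeros((d, d))
        b_vec = np.zeros(d)
        s2 = reg.sigma2[k]

        # likelihood contributions: W = [1 | X | I | I]
        Q[0, 0] = omega.sum()
        b_vec[0] = resid.sum()
        if has_X:
            wX = omega[:, None] * X
            Q[0, 1 : 1 + P] = omega @ X
            Q[1 : 1 + P, 0] = Q[0, 1 : 1 + P]
            Q[1 : 1 + P, 1 : 1 + P] = X.T @ wX
            b_vec[1 : 1 + P] = X.T @ resid
        if has_gen:
            Q[0, iu] = omega
            Q[iu, 0] = omega
            if has_X:
                Q[1 : 1 + P, iu] = wX.T
                Q[iu, 1 : 1 + P] = wX
            q_u = Q[1 + P : 1 + P + N, 1 + P : 1 + P + N]
            q_u[np.diag_indices(N)] += omega
            q_ue = Q[1 + P : 1 + P + N, 1 + P + N :]
            q_ue[np.diag_indices(N)] += omega
            q_eu = Q[1 + P + N :, 1 + P : 1 + P + N]
            q_eu[np.diag_indices(N)] += omega
            b_vec[iu] = resid
        Q[0, ie] = omega
        Q[ie, 0] = omega
        if has_X:
            Q[1 : 1 + P, ie] = wX.T
            Q[ie, 1 : 1 + P] = wX
        q_e = Q[ie, ie]
        q_e[np.diag_indices(N)] += omega
        b_vec[ie] = resid

        # prior precision
        Q[0, 0] += 1.0 / (reg.tau * s2)
        if has_X:
            Q[1 : 1 + P, 1 : 1 + P] += np.eye(P) / hyper.beta_sd**2
        if has_gen:
            q_u += Ainv / (reg.gamma[k] * s2)
        q_e[np.diag_indices(N)] += 1.0 / s2

        c, low = linalg.cho_factor(Q, lower=True)
        mean = linalg.cho_solve((c, low), b_vec)
        draw = mean + linalg.solve_triangular(
            c, rng.standard_normal(d), lower=low, trans="T"
        )

        alpha[k] = draw[0]
        if has_X:
            beta[:, k] = draw[1 : 1 + P]
        if has_gen:
            u[:, k] = draw[iu]
        eps[:, k] = draw[ie]
        eta[:, k] = draw[0] + (X @ beta[:, k] if has_X else 0.0)
        if has_gen:
            eta[:, k] += u[:, k]
        eta[:, k] += eps[:, k]

    new = replace(reg, alpha=alpha, beta=beta, u=u, eps=eps)
    return new, eta


def sample_variances(
    reg: RegressionState,
    Ainv: np.ndarray | None,
    hyper: Hyperpriors,
    rng: np.random.Generator,
) -> RegressionState:
    """Conjugate inverse-gamma draws of sigma2_k, tau, and gamma_k."""
    N, K = reg.eps.shape
    has_gen = reg.u is not None

    uAu = None
    if has_gen:
        uAu = np.array([reg.u[:, k] @ Ainv @ reg.u[:, k] for k in range(K)])

    sigma2 = np.empty(K)
    for k in range(K):
        m = N + 1 + (N if has_gen else 0)
        quad = (reg.eps[:, k] ** 2).sum() + reg.alpha[k] ** 2 / reg.tau
        if has_gen:
            quad += uAu[k] / reg.gamma[k]
        sigma2[k] = 1.0 / rng.gamma(
            hyper.sigma2_shape + m / 2.0, 1.0 / (hyper.sigma2_rate + quad / 2.0)
        )

    tau = 1.0 / rng.gamma(
        hyper.tau_shape + K / 2.0,
        1.0 / (hyper.tau_rate + 0.5 * float((reg.alpha**2 / sigma2).sum())),
    )

    gamma = None
    if has_gen:
        gamma = np.empty(K)
        for k in range(K):
            gamma[k] = 1.0 / rng.gamma(
                hyper.gamma_shape + N / 2.0,
                1.0 / (hyper.gamma_rate + uAu[k] / (2.0 * sigma2[k])),
            )
    return replace(reg, sigma2=sigma2, tau=float(tau), gamma=gamma)


def _initial_regression_state(
    N: int, K: int, P: int, has_gen: bool, weights: np.ndarray | None
) -> RegressionState:
    if weights is not None:
        a = np.log(np.clip(weights, 1e-8, None))
        a = a - a.mean()
    else:
        a = np.zeros(K)
    # unit variances: the default hyperpriors have undefined means (shape < 1)
    return RegressionState(
        alpha=a,
        beta=np.zeros((P, K)),
        u=np.zeros((N, K)) if has_gen else None,
        eps=np.zeros((N, K)),
        sigma2=np.ones(K),
        tau=1.0,
        gamma=np.ones(K) if has_gen else None,
    )


def run_chain(
    data: BinnedDataset,
    K: int,
    config: SamplerConfig,
    chain_id: int = 0,
    X: np.ndarray | None = None,
    A: np.ndarray | None = None,
    hyper: Hyperpriors = Hyperpriors(),
    z0: np.ndarray | None = None,
    init_weights: np.ndarray | None = None,
    progress: bool = False,
) -> PosteriorSamples:
    """Run one Gibbs chain and return its thinned, burned-in draws.

    ``chain_id`` offsets the seed so multiple chains are independent but the
    whole run is reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + chain_id)
    N = data.n_animals
    has_X = X is not None and X.shape[1] > 0
    P = X.shape[1] if has_X else 0
    has_gen = A is not None
    Ainv = _prepare_A_inverse(A, config.jitter)

    if z0 is None:
        z0, _ = initial_assignments(data, K, rng)
    z = np.asarray(z0, dtype=np.int64).copy()
    reg = _initial_regression_state(N, K, P, has_gen, init_weights)
    eta = reg.eta(X if has_X else None)
    totals = data.focals_per_animal

    kept_at = config.kept_iterations()
    keep_mask = np.zeros(config.n_iterations, dtype=bool)
    keep_mask[kept_at] = True
    n_keep = int(keep_mask.sum())

    Lmax = int(data.n_levels.max())
    out = PosteriorSamples(
        theta=np.empty((n_keep, K, data.n_behaviors, Lmax)),
        alpha=np.empty((n_keep, K)),
        beta=np.empty((n_keep, P, K)),
        u=np.empty((n_keep, N, K)) if has_gen else None,
        eps=np.empty((n_keep, N, K)),
        sigma2=np.empty((n_keep, K)),
        tau=np.empty(n_keep),
        gamma=np.empty((n_keep, K)) if has_gen else None,
        z=np.empty((n_keep, data.n_obs), dtype=np.int32),
        chain=np.full(n_keep, chain_id, dtype=np.int32),
        iteration=np.empty(n_keep, dtype=np.int64),
        n_levels=data.n_levels.copy(),
        animal_ids=list(data.animal_ids),
        covariate_names=[],
    )

    s = 0
    iterator = range(config.n_iterations)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=f"chain {chain_id}")
    for it in iterator:
        theta = sample_state_params(data, z, K, rng, hyper.dirichlet_conc)
        pi = softmax(eta, axis=1)
        z = sample_assignments(data, theta, pi, rng)
        counts = np.bincount(
            data.animal_index * K + z, minlength=N * K
        ).reshape(N, K)
        reg, eta = sample_regression_block(
            counts, totals, X if has_X else None, Ainv, reg, hyper, rng, eta
        )
        reg = sample_variances(reg, Ainv, hyper, rng)

        if keep_mask[it]:
            out.theta[s] = theta.theta
            out.alpha[s] = reg.alpha
            out.beta[s] = reg.beta
            if has_gen:
                out.u[s] = reg.u
                out.gamma[s] = reg.gamma
            out.eps[s] = reg.eps
            out.sigma2[s] = reg.sigma2
            out.tau[s] = reg.tau
            out.z[s] = z
            out.iteration[s] = it
            s += 1

    burn = config.burn_in_kept
    sl = slice(burn, None)
    return PosteriorSamples(
        theta=out.theta[sl],
        alpha=out.alpha[sl],
        beta=out.beta[sl],
        u=out.u[sl] if has_gen else None,
        eps=out.eps[sl],
        sigma2=out.sigma2[sl],
        tau=out.tau[sl],
        gamma=out.gamma[sl] if has_gen else None,
        z=out.z[sl],
        chain=out.chain[sl],
        iteration=out.iteration[sl],
        n_levels=out.n_levels,
        animal_ids=out.animal_ids,
        covariate_names=out.covariate_names,
    )


def _concat_samples(parts: list[PosteriorSamples]) -> PosteriorSamples:
    first = parts[0]
    cat = lambda f: np.concatenate([getattr(p, f) for p in parts])  # noqa: E731
    return PosteriorSamples(
        theta=cat("theta"),
        alpha=cat("alpha"),
        beta=cat("beta"),
        u=cat("u") if first.u is not None else None,
        eps=cat("eps"),
        sigma2=cat("sigma2"),
        tau=cat("tau"),
        gamma=cat("gamma") if first.gamma is not None else None,
        z=cat("z"),
        chain=cat("chain"),
        iteration=cat("iteration"),
        n_levels=first.n_levels,
        animal_ids=first.animal_ids,
        covariate_names=first.covariate_names,
    )


def fit_model(
    data: BinnedDataset,
    K: int,
    config: SamplerConfig,
    X: np.ndarray | None = None,
    A: np.ndarray | None = None,
    hyper: Hyperpriors = Hyperpriors(),
    n_starts: int = 10,
    init_noise: float = 0.5,
    covariate_names: list[str] | None = None,
    progress: bool = False,
) -> PosteriorSamples:
    """Full fitting procedure: flat-model EM warm start, then Gibbs chains.

    The flat fit is shared across chains; each chain draws its own initial
    assignments from the flat memberships with its own RNG stream.
    """
    init_rng = np.random.default_rng(config.seed)
    from .initialization import draw_initial_assignments, fit_flat_model

    flat = fit_flat_model(
        data, K, n_starts=n_starts, noise_scale=init_noise, rng=init_rng
    )
    parts = []
    for c in range(config.n_chains):
        chain_rng = np.random.default_rng(config.seed + c)
        z0 = draw_initial_assignments(flat, chain_rng)
        parts.append(
            run_chain(
                data,
                K,
                config,
                chain_id=c,
                X=X,
                A=A,
                hyper=hyper,
                z0=z0,
                init_weights=flat.weights,
                progress=progress,
            )
        )
    samples = _concat_samples(parts)
    samples.covariate_names = list(covariate_names or [])
    return samples


def geweke_joint_chain(
    n_iter: int,
    N: int,
    K: int,
    B: int,
    focals_per_animal: int,
    hyper: Hyperpriors,
    rng: np.random.Generator,
    n_levels: int = 3,
    X: np.ndarray | None = None,
    A: np.ndarray | None = None,
    thin: int = 1,
) -> dict[str, np.ndarray]:
    """Successive-conditional simulator for the joint-distribution test.

    Alternates (i) one full Gibbs parameter scan conditional on the data and
    (ii) re-simulation of the data conditional on (z, theta).  If every
    conditional is correct, the marginal distribution of every parameter
    equals its prior, which the test suite checks by comparing quantiles.
    """
    has_X = X is not None and X.shape[1] > 0
    P = X.shape[1] if has_X else 0
    has_gen = A is not None
    Ainv = _prepare_A_inverse(A, 1e-10)
    n_obs = N * focals_per_animal
    animal_index = np.repeat(np.arange(N), focals_per_animal)
    totals = np.full(N, focals_per_animal)
    nl = np.full(B, n_levels, dtype=np.int64)

    def draw_prior_reg() -> RegressionState:
        sigma2 = 1.0 / rng.gamma(hyper.sigma2_shape, 1.0 / hyper.sigma2_rate, size=K)
        tau = 1.0 / rng.gamma(hyper.tau_shape, 1.0 / hyper.tau_rate)
        gamma = (
            1.0 / rng.gamma(hyper.gamma_shape, 1.0 / hyper.gamma_rate, size=K)
            if has_gen
            else None
        )
        alpha = rng.normal(0.0, np.sqrt(tau * sigma2))
        beta = rng.normal(0.0, hyper.beta_sd, size=(P, K))
        eps = rng.normal(0.0, np.sqrt(sigma2)[None, :], size=(N, K))
        u = None
        if has_gen:
            L = np.linalg.cholesky(A + 1e-10 * np.eye(N))
            u = np.column_stack(
                [
                    np.sqrt(gamma[k] * sigma2[k]) * (L @ rng.normal(size=N))
                    for k in range(K)
                ]
            )
        return RegressionState(
            alpha=alpha, beta=beta, u=u, eps=eps, sigma2=sigma2, tau=float(tau), gamma=gamma
        )

    def draw_prior_theta() -> StateParams:
        g = rng.gamma(hyper.dirichlet_conc, size=(K, B, n_levels))
        return StateParams(theta=g / g.sum(axis=2, keepdims=True), n_levels=nl)

    def simulate_y(z: np.ndarray, theta: StateParams) -> BinnedDataset:
        cum = np.cumsum(theta.theta, axis=2)
        unif = rng.random(size=(n_obs, B))
        levels = np.empty((n_obs, B), dtype=np.int64)
        for b in range(B):
            levels[:, b] = (unif[:, b : b + 1] > cum[z, b, :]).sum(axis=1) + 1
        levels = np.minimum(levels, n_levels)
        return BinnedDataset(
            levels=levels,
            animal_index=animal_index,
            animal_ids=[f"A{i}" for i in range(N)],
            behavior_names=[f"b{j}" for j in range(B)],
            n_levels=nl,
        )

    reg = draw_prior_reg()
    theta = draw_prior_theta()
    eta = reg.eta(X if has_X else None)
    pi = softmax(eta, axis=1)
    z = np.argmax(
        np.log(np.clip(pi, 1e-300, None))[animal_index]
        + rng.gumbel(size=(n_obs, K)),
        axis=1,
    )
    data = simulate_y(z, theta)

    keep = {
        "alpha": [],
        "beta": [],
        "sigma2": [],
        "tau": [],
        "gamma": [],
        "eps": [],
    }
    for it in range(n_iter):
        theta = sample_state_params(data, z, K, rng, hyper.dirichlet_conc)
        pi = softmax(eta, axis=1)
        z = sample_assignments(data, theta, pi, rng)
        counts = np.bincount(animal_index * K + z, minlength=N * K).reshape(N, K)
        reg, eta = sample_regression_block(
            counts, totals, X if has_X else None, Ainv, reg, hyper, rng, eta
        )
        reg = sample_variances(reg, Ainv, hyper, rng)
        data = simulate_y(z, theta)
        if it % thin == 0:
            keep["alpha"].append(reg.alpha.copy())
            keep["beta"].append(reg.beta.copy())
            keep["sigma2"].append(reg.sigma2.copy())
            keep["tau"].append(reg.tau)
            keep["eps"].append(reg.eps[0].copy())
            if has_gen:
                keep["gamma"].append(reg.gamma.copy())
    return {k: np.asarray(v) for k, v in keep.items() if len(v)}
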