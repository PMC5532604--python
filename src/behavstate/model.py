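"""Core model containers and densities for the behavioral-state topic model.

The generative model: each focal observation ``f`` of animal ``i`` carries a
latent state ``z_{i,f} in 1..K``.  Conditional on its state, the observation's
level vector is a product of independent categorical draws, one per behavior,
with per-state probability tables ``theta``.  The per-animal probabilities of
the states — the animal's *social phenotype* ``pi_i`` — come from a
multinomial-logistic mixed-effects regression on unbounded propensities

    eta_{i,k} = alpha_k + X_i' beta_k + u_{i,k} + eps_{i,k}
    pi_i      = softmax(eta_i)

with random effects

    eps_{i,k} ~ N(0, sigma2_k)            individual deviation
    alpha_k   ~ N(0, tau * sigma2_k)      baseline state propensity
    u_{.,k}   ~ N(0, gamma_k sigma2_k A)  additive genetic effect

where A is the additive relatedness matrix.  Scaling tau and gamma_k by the
per-state variance sigma2_k keeps the regression layer fully conjugate, which
is what lets the Gibbs sampler draw the whole regression block jointly.
Approximate narrow-sense heritability of state-k propensity is
``gamma_k / (1 + gamma_k)``.

All K propensities are kept (the softmax is overparameterized; the priors
provide soft identification); baseline subtraction is applied only when
reporting coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .data import BinnedDataset

__all__ = [
    "StateParams",
    "Assignments",
    "CovariateMatrix",
    "RegressionState",
    "Phenotype",
    "Hyperpriors",
    "softmax",
    "state_log_likelihood",
    "loglik_matrix",
    "animal_log_likelihood",
    "propensity",
    "joint_log_density",
    "build_design",
]


def softmax(eta: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax (max-shifted) along ``axis``."""
    eta = np.asarray(eta, dtype=float)
    shifted = eta - np.max(eta, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class StateParams:
    """Per-state categorical tables theta over each behavior's levels.

    Stored padded: ``theta[k, b, :n_levels[b]]`` is the probability vector of
    behavior b in state k; padding beyond ``n_levels[b]`` is zero.
    """

    theta: np.ndarray  # (K, B, Lmax)
    n_levels: np.ndarray  # (B,)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.n_levels = np.asarray(self.n_levels, dtype=np.int64)
        K, B, Lmax = self.theta.shape
        if B != len(self.n_levels):
            raise ValueError("n_levels length must match behaviors")
        if self.n_levels.max(initial=0) > Lmax:
            raise ValueError("n_levels exceed padded width")
        if np.any(self.theta < 0):
            raise ValueError("theta must be non-negative")
        sums = self.theta.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("each theta^(k,b) must sum to 1")
        pad = self._pad_mask()
        if np.any(self.theta[:, pad]):
            raise ValueError("padding beyond n_levels must be zero")

    def _pad_mask(self) -> np.ndarray:
        Lmax = self.theta.shape[2]
        return np.arange(Lmax)[None, :] >= self.n_levels[:, None]  # (B, Lmax)

    @property
    def n_states(self) -> int:
        return self.theta.shape[0]

    @property
    def n_behaviors(self) -> int:
        return self.theta.shape[1]

    def log_theta(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.theta)

    def flatten_valid(self) -> np.ndarray:
        """(K, sum_b n_levels[b]) concatenation of the valid entries."""
        keep = ~self._pad_mask()
        return self.theta[:, keep]


@dataclass
class Assignments:
    """Latent state labels z per focal observation, with per-animal counts."""

    z: np.ndarray  # (N_obs,) int in 0..K-1 (0-based internally)
    n_animals: int
    n_states: int
    animal_index: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int64)
        self.animal_index = np.asarray(self.animal_index, dtype=np.int64)
        if self.z.size and (self.z.min() < 0 or self.z.max() >= self.n_states):
            raise ValueError("state labels out of range")

    @property
    def counts(self) -> np.ndarray:
        """n_{i,k}: focal observations of animal i assigned to state k."""
        flat = self.animal_index * self.n_states + self.z
        return np.bincount(flat, minlength=self.n_animals * self.n_states).reshape(
            self.n_animals, self.n_states
        )

    @property
    def totals(self) -> np.ndarray:
        """n_i: total focal observations per animal."""
        return np.bincount(self.animal_index, minlength=self.n_animals)


@dataclass
class CovariateMatrix:
    """Animal-level fixed-effect design matrix with column metadata."""

    X: np.ndarray  # (N, P)
    columns: list[str]
    animal_ids: list[str]
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.animal_ids), len(self.columns)):
            raise ValueError("X shape must be (animals, columns)")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("design matrix contains missing/non-finite values")

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


def build_design(
    covariates: pd.DataFrame,
    numeric: list[str] | None = None,
    categorical: list[str] | None = None,
    ordered: dict[str, list[str]] | None = None,
    interactions: list[tuple[str, str]] | None = None,
    standardize: bool = True,
) -> CovariateMatrix:
    """Build a fixed-effect design matrix from an animal covariate table.

    Numeric covariates are centered and scaled by default (the N(0,1) prior
    on beta presumes standardized inputs).  Categorical covariates are
    dummy-coded against their first level; ordered covariates (e.g. dominance
    rank low/medium/high) are mapped to centered numeric scores
    ``-1, 0, 1, ...``.  Interactions multiply two already-encoded columns.
    """
    if "animal_id" not in covariates.columns:
        raise ValueError("covariate table must have an animal_id column")
    covariates = covariates.reset_index(drop=True)
    ids = covariates["animal_id"].astype(str).tolist()
    numeric = numeric or []
    categorical = categorical or []
    ordered = ordered or {}
    interactions = interactions or []

    cols: dict[str, np.ndarray] = {}
    centers: dict[str, float] = {}
    scales: dict[str, float] = {}
    for c in numeric:
        x = covariates[c].to_numpy(dtype=float)
        mu, sd = (x.mean(), x.std()) if standardize else (0.0, 1.0)
        sd = sd if sd > 0 else 1.0
        cols[c] = (x - mu) / sd
        centers[c], scales[c] = mu, sd
    for c, lvls in ordered.items():
        codes = covariates[c].astype(str).map({l: i for i, l in enumerate(lvls)})
        if codes.isna().any():
            bad = sorted(set(covariates[c][codes.isna()].astype(str)))
            raise ValueError(f"unknown levels {bad} for ordered covariate {c!r}")
        score = codes.to_numpy(dtype=float) - (len(lvls) - 1) / 2.0
        cols[c] = score
        centers[c], scales[c] = (len(lvls) - 1) / 2.0, 1.0
    for c in categorical:
        series = covariates[c].astype(str)
        lvls = sorted(series.unique())
        for l in lvls[1:]:
            name = f"{c}[{l}]"
            cols[name] = (series == l).to_numpy(dtype=float)
            centers[name], scales[name] = 0.0, 1.0
    for a, b in interactions:
        if a not in cols or b not in cols:
            raise ValueError(f"interaction terms must reference encoded columns: {(a, b)}")
        name = f"{a}:{b}"
        cols[name] = cols[a] * cols[b]
        centers[name], scales[name] = 0.0, 1.0

    names = list(cols)
    X = np.column_stack([cols[c] for c in names]) if names else np.empty((len(ids), 0))
    return CovariateMatrix(
        X=X,
        columns=names,
        animal_ids=ids,
        centers=np.array([centers[c] for c in names]),
        scales=np.array([scales[c] for c in names]),
    )


@dataclass
class RegressionState:
    """Current values of the phenotype-regression layer."""

    alpha: np.ndarray  # (K,)
    beta: np.ndarray  # (P, K)
    u: np.ndarray | None  # (N, K) genetic effects, None when no pedigree
    eps: np.ndarray  # (N, K)
    sigma2: np.ndarray  # (K,)
    tau: float
    gamma: np.ndarray | None  # (K,)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if np.any(self.sigma2 <= 0) or self.tau <= 0:
            raise ValueError("variance components must be positive")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if np.any(self.gamma <= 0):
                raise ValueError("gamma must be positive")

    def eta(self, X: np.ndarray | None) -> np.ndarray:
        return propensity(self.alpha, X, self.beta, self.u, self.eps)


@dataclass
class Phenotype:
    """Propensities eta and their softmax pi, one row per animal."""

    eta: np.ndarray
    pi: np.ndarray = field(init=False)

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        self.pi = softmax(self.eta, axis=1)


@dataclass(frozen=True)
class Hyperpriors:
    """Prior constants.

    Defaults: Dirichlet(1) on each theta table, N(0,1) on beta,
    InvGamma(0.005, 0.0005) on sigma2_k and tau, and InvGamma(0.165, 0.0165)
    on gamma_k — the latter chosen so the implied prior on approximate
    heritability gamma/(1+gamma) is roughly symmetric with substantial mass
    near both 0 and 1.
    """

    dirichlet_conc: float = 1.0
    beta_sd: float = 1.0
    sigma2_shape: float = 0.005
    sigma2_rate: float = 0.0005
    tau_shape: float = 0.005
    tau_rate: float = 0.0005
    gamma_shape: float = 0.165
    gamma_rate: float = 0.0165

    def __post_init__(self):
        for f in (
            self.dirichlet_conc,
            self.beta_sd,
            self.sigma2_shape,
            self.sigma2_rate,
            self.tau_shape,
            self.tau_rate,
            self.gamma_shape,
            self.gamma_rate,
        ):
            if f <= 0:
                raise ValueError("hyperprior constants must be strictly positive")


def state_log_likelihood(y_row: np.ndarray, k: int, theta: StateParams) -> float:
    """log p(y | z = k, theta) = sum_b log theta_{y_b}^{(k,b)} (1-based y)."""
    y_row = np.asarray(y_row, dtype=np.int64)
    if np.any(y_row < 1) or np.any(y_row > theta.n_levels):
        raise ValueError("observed levels out of range")
    with np.errstate(divide="ignore"):
        logs = np.log(theta.theta[k, np.arange(theta.n_behaviors), y_row - 1])
    return float(logs.sum())


def loglik_matrix(data: BinnedDataset, theta: StateParams) -> np.ndarray:
    """(K, N_obs) matrix of per-state log-likelihoods for every observation."""
    if np.any(data.n_levels != theta.n_levels):
        raise ValueError("dataset and state parameters disagree on level counts")
    logt = theta.log_theta()  # (K, B, Lmax)
    lev = data.levels - 1  # (N, B)
    out = np.zeros((theta.n_states, data.n_obs))
    for b in range(data.n_behaviors):
        out += logt[:, b, lev[:, b]]
    return out


def animal_log_likelihood(
    rows: np.ndarray, z: np.ndarray, theta: StateParams
) -> float:
    """Sum of per-row state log-likelihoods at the assigned states (the log
    of the product of likelihoods over an animal's focal observations)."""
    rows = np.atleast_2d(np.asarray(rows, dtype=np.int64))
    z = np.atleast_1d(np.asarray(z, dtype=np.int64))
    if rows.shape[0] == 0:
        return 0.0
    if len(z) != rows.shape[0]:
        raise ValueError("one state label per row required")
    return float(
        sum(state_log_likelihood(rows[f], int(z[f]), theta) for f in range(rows.shape[0]))
    )


def propensity(
    alpha: np.ndarray,
    X: np.ndarray | None,
    beta: np.ndarray,
    u: np.ndarray | None,
    eps: np.ndarray,
) -> np.ndarray:
    """eta_{i,k} = alpha_k + X_i' beta_k + u_{i,k} + eps_{i,k}."""
    alpha = np.asarray(alpha, dtype=float)
    eps = np.asarray(eps, dtype=float)
    eta = alpha[None, :] + eps
    if X is not None and np.asarray(beta).size:
        X = np.asarray(X, dtype=float)
        beta = np.asarray(beta, dtype=float)
        if X.shape[1] != beta.shape[0] or beta.shape[1] != alpha.shape[0]:
            raise ValueError("covariate/coefficient shapes not conformable")
        eta = eta + X @ beta
    if u is not None:
        u = np.asarray(u, dtype=float)
        if u.shape != eps.shape:
            raise ValueError("u and eps shapes must match")
        eta = eta + u
    return eta


def _invgamma_logpdf(x, shape, rate):
    return stats.invgamma.logpdf(x, a=shape, scale=rate)


def joint_log_density(
    data: BinnedDataset,
    assign: Assignments,
    theta: StateParams,
    reg: RegressionState,
    X: np.ndarray | None = None,
    A: np.ndarray | None = None,
    hyper: Hyperpriors = Hyperpriors(),
) -> float:
    """Unnormalized log joint of data, latents and parameters.

    Sum of the categorical data likelihood, the multinomial assignment prior
    under pi = softmax(eta), the random-effect Gaussians, and the hyperprior
    densities.  Used for sampler validation and convergence diagnostics.
    """
    K = theta.n_states
    N = data.n_animals

    ll = loglik_matrix(data, theta)
    data_term = float(ll[assign.z, np.arange(data.n_obs)].sum())

    eta = reg.eta(X)
    logpi = eta - logsumexp(eta, axis=1, keepdims=True)
    assign_term = float((assign.counts * logpi).sum())

    # random effects (shared sigma2_k scaling) and hyperpriors
    re_term = float(
        stats.norm.logpdf(
            reg.alpha, 0.0, np.sqrt(reg.tau * reg.sigma2)
        ).sum()
        + stats.norm.logpdf(reg.eps, 0.0, np.sqrt(reg.sigma2)[None, :]).sum()
    )
    if reg.u is not None:
        if A is None:
            raise ValueError("A required when genetic effects present")
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            raise ValueError("A must be positive definite")
        Ainv = np.linalg.inv(A)
        for k in range(K):
            v = reg.gamma[k] * reg.sigma2[k]
            quad = reg.u[:, k] @ Ainv @ reg.u[:, k] / v
            re_term += -0.5 * (N * np.log(2 * np.pi * v) + logdet + quad)

    prior_term = float(
        _invgamma_logpdf(reg.sigma2, hyper.sigma2_shape, hyper.sigma2_rate).sum()
        + _invgamma_logpdf(reg.tau, hyper.tau_shape, hyper.tau_rate)
    )
    if reg.gamma is not None:
        prior_term += float(
            _invgamma_logpdf(reg.gamma, hyper.gamma_shape, hyper.gamma_rate).sum()
        )
    if reg.beta.size:
        prior_term += float(stats.norm.logpdf(reg.beta, 0.0, hyper.beta_sd).sum())
    # symmetric Dirichlet(conc) prior over every state/behavior table
    conc = hyper.dirichlet_conc
    for b in range(theta.n_behaviors):
        L = int(theta.n_levels[b])
        tb = theta.theta[:, b, :L]
        with np.errstate(divide="ignore"):
            prior_term += float(((conc - 1.0) * np.log(np.clip(tb, 1e-300, None))).sum())
        prior_term += float(K * (gammaln(L * conc) - L * gammaln(conc)))
    return data_term + assign_term + re_term + prior_term
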