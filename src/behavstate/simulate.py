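"""Synthetic data with the model's assumed generative structure.

Two modes:

* the basic recovery simulation — states drawn by softmax-transforming
  i.i.d. standard-normal level propensities, per-animal state propensities
  drawn around shared normal baselines:

      lambda_l^{(k,b)} ~ N(0, 1)     theta^{(k,b)} = softmax(lambda^{(k,b)})
      alpha_k ~ N(0, 0.25)           eta_{i,k} ~ N(alpha_k, 0.0625)

  (second arguments read as variances throughout, consistent with the
  random-effect layer), with 200 individuals x 100 focals, 30 behaviors and
  3 levels per behavior under the default recovery-study settings;

* an extended mode that composes the full regression layer — covariates with
  fixed effects, a simulated pedigree, and additive genetic effects
  u_{.,k} ~ N(0, gamma_k sigma2_k A) — for end-to-end genetic-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BinnedDataset
from .model import CovariateMatrix, StateParams, softmax
from .pedigree import Pedigree, RelatednessMatrix, kinship_matrix, relatedness_matrix

__all__ = [
    "SimulationTruth",
    "simulate_states",
    "simulate_phenotypes",
    "simulate_observations",
    "simulate_full_model",
    "simulate_pedigree",
    "simulate_recovery_dataset",
]

# defaults of the basic recovery simulation
DEFAULT_N_INDIVIDUALS = 200
DEFAULT_N_FOCALS = 100
DEFAULT_N_BEHAVIORS = 30
DEFAULT_N_LEVELS = 3
STATE_PROPENSITY_VAR = 1.0  # lambda ~ N(0, 1)
ETA_VAR = 0.0625  # eta_{i,k} ~ N(alpha_k, 0.0625)
ALPHA_VAR = 0.25  # alpha_k ~ N(0, 0.25)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generators for recovery scoring."""

    theta: StateParams
    eta: np.ndarray  # (N, K)
    pi: np.ndarray  # (N, K)
    z: np.ndarray  # (N_obs,) 0-based
    settings: dict
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    u: np.ndarray | None = None
    eps: np.ndarray | None = None


def simulate_states(
    K: int, B: int, n_levels: int = DEFAULT_N_LEVELS, rng: np.random.Generator | None = None
) -> StateParams:
    """Draw K states: i.i.d. N(0,1) level propensities, softmaxed per behavior."""
    rng = np.random.default_rng(rng)
    if K < 1 or B < 1:
        raise ValueError("K and B must be >= 1")
    lam = rng.normal(0.0, np.sqrt(STATE_PROPENSITY_VAR), size=(K, B, n_levels))
    theta = softmax(lam, axis=2)
    return StateParams(theta=theta, n_levels=np.full(B, n_levels, dtype=np.int64))


def simulate_phenotypes(
    N: int, K: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-animal propensities eta ~ N(alpha_k, 0.0625), alpha ~ N(0, 0.25)."""
    rng = np.random.default_rng(rng)
    if N < 1 or K < 1:
        raise ValueError("N and K must be >= 1")
    alpha = rng.normal(0.0, np.sqrt(ALPHA_VAR), size=K)
    eta = rng.normal(alpha[None, :], np.sqrt(ETA_VAR), size=(N, K))
    return eta, softmax(eta, axis=1)


def simulate_observations(
    theta: StateParams,
    pi: np.ndarray,
    focals_per_individual: int,
    rng: np.random.Generator | None = None,
    eta: np.ndarray | None = None,
    animal_ids: list[str] | None = None,
    extra_truth: dict | None = None,
) -> tuple[BinnedDataset, SimulationTruth]:
    """Sample a state per focal from pi, then levels per behavior from theta."""
    rng = np.random.default_rng(rng)
    pi = np.asarray(pi, dtype=float)
    N, K = pi.shape
    if K != theta.n_states:
        raise ValueError("pi columns must match the number of states")
    B = theta.n_behaviors
    F = focals_per_individual
    n_obs = N * F

    animal_index = np.repeat(np.arange(N), F)
    # Gumbel-max categorical draws, vectorized over observations
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    z = np.argmax(logpi[animal_index] + rng.gumbel(size=(n_obs, K)), axis=1)

    levels = np.empty((n_obs, B), dtype=np.int64)
    unif = rng.random(size=(n_obs, B))
    cum = np.cumsum(theta.theta, axis=2)  # (K, B, Lmax)
    for b in range(B):
        # inverse-CDF lookup: count of cumulative masses below the uniform
        levels[:, b] = (unif[:, b : b + 1] > cum[z, b, :]).sum(axis=1) + 1
    levels = np.minimum(levels, theta.n_levels[None, :])

    if animal_ids is None:
        animal_ids = [f"A{i:04d}" for i in range(N)]
    data = BinnedDataset(
        levels=levels,
        animal_index=animal_index,
        animal_ids=list(animal_ids),
        behavior_names=[f"b{j:02d}" for j in range(B)],
        n_levels=theta.n_levels.copy(),
        focal_id=np.array(
            [f"{animal_ids[i]}_f{f:03d}" for i in range(N) for f in range(F)],
            dtype=object,
        ),
    )
    settings = {
        "K": K,
        "N": N,
        "focals_per_individual": F,
        "B": B,
    }
    if extra_truth:
        settings.update(extra_truth.pop("settings", {}))
    truth = SimulationTruth(
        theta=theta,
        eta=eta if eta is not None else logpi,
        pi=pi,
        z=z,
        settings=settings,
        **(extra_truth or {}),
    )
    return data, truth


def simulate_recovery_dataset(
    K: int,
    N: int = DEFAULT_N_INDIVIDUALS,
    focals_per_individual: int = DEFAULT_N_FOCALS,
    B: int = DEFAULT_N_BEHAVIORS,
    n_levels: int = DEFAULT_N_LEVELS,
    rng: np.random.Generator | None = None,
) -> tuple[BinnedDataset, SimulationTruth]:
    """The basic recovery simulation at its default scale."""
    rng = np.random.default_rng(rng)
    theta = simulate_states(K, B, n_levels, rng)
    eta, pi = simulate_phenotypes(N, K, rng)
    return simulate_observations(theta, pi, focals_per_individual, rng, eta=eta)


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_generation: int,
    rng: np.random.Generator | None = None,
    full_sib_litter: int = 1,
) -> Pedigree:
    """Forward random-mating pedigree simulation (acyclic by construction).

    Each generation draws ``offspring_per_generation`` mating pairs uniformly
    from the previous generation and produces ``full_sib_litter`` full
    siblings per pair; litters > 1 create the strong relatedness structure
    useful for genetic-recovery tests.
    """
    rng = np.random.default_rng(rng)
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    records: list[tuple[str, str, str]] = [
        (f"G0_{i:03d}", "", "") for i in range(n_founders)
    ]
    prev = [r[0] for r in records]
    for g in range(1, n_generations):
        current = []
        for j in range(offspring_per_generation):
            sire, dam = rng.choice(prev, size=2, replace=False)
            for c in range(full_sib_litter):
                cid = f"G{g}_{j:03d}_{c}"
                records.append((cid, str(sire), str(dam)))
                current.append(cid)
        prev = current if current else prev
    return Pedigree(tuple(records))


def simulate_full_model(
    N: int,
    K: int,
    B: int,
    focals_per_individual: int,
    rng: np.random.Generator | None = None,
    n_levels: int = DEFAULT_N_LEVELS,
    n_covariates: int = 2,
    beta: np.ndarray | None = None,
    pedigree: Pedigree | None = None,
    sigma2: float | np.ndarray = 1.0,
    tau: float = 0.25,
    gamma: float | np.ndarray = 1.0,
) -> tuple[BinnedDataset, CovariateMatrix, RelatednessMatrix, SimulationTruth]:
    """Generate from the full regression layer including genetic effects.

    Covariate defaults: one binary and one standardized continuous covariate
    with coefficients drawn N(0,1) unless ``beta`` is given.  If no pedigree
    is supplied, one with 3 generations of full-sib litters is simulated and
    the youngest N individuals become the study subjects.  ``gamma = 0``
    switches the genetic component off (u identically zero).
    """
    rng = np.random.default_rng(rng)
    sigma2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (K,)).copy()
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (K,)).copy()
    if np.any(sigma2 <= 0) or tau < 0 or np.any(gamma < 0):
        raise ValueError("variance parameters must be non-negative (sigma2 positive)")

    if pedigree is None:
        litter = 4
        pairs = max(1, int(np.ceil(N / (2 * litter))))
        pedigree = simulate_pedigree(
            n_founders=max(8, pairs),
            n_generations=3,
            offspring_per_generation=pairs,
            rng=rng,
            full_sib_litter=litter,
        )
    ids = pedigree.ids
    if len(ids) < N:
        raise ValueError("pedigree has fewer individuals than requested subjects")
    subjects = ids[-N:]
    A = relatedness_matrix(kinship_matrix(pedigree, subjects))

    # covariates: first binary, rest standard normal
    Xcols = [rng.integers(0, 2, size=N).astype(float)]
    for _ in range(1, n_covariates):
        Xcols.append(rng.normal(size=N))
    X = np.column_stack(Xcols) if n_covariates else np.empty((N, 0))
    X = X - X.mean(axis=0, keepdims=True)
    covs = CovariateMatrix(
        X=X,
        columns=[f"x{j}" for j in range(n_covariates)],
        animal_ids=list(subjects),
    )
    if beta is None:
        beta = rng.normal(0.0, 1.0, size=(n_covariates, K))
    beta = np.asarray(beta, dtype=float).reshape(n_covariates, K)

    alpha = rng.normal(0.0, np.sqrt(tau * sigma2), size=K)
    eps = rng.normal(0.0, np.sqrt(sigma2)[None, :], size=(N, K))
    u = np.zeros((N, K))
    if np.any(gamma > 0):
        L = np.linalg.cholesky(A.A + 1e-10 * np.eye(N))
        for k in range(K):
            if gamma[k] > 0:
                u[:, k] = np.sqrt(gamma[k] * sigma2[k]) * (L @ rng.normal(size=N))
    eta = alpha[None, :] + X @ beta + u + eps
    pi = softmax(eta, axis=1)

    theta = simulate_states(K, B, n_levels, rng)
    data, truth = simulate_observations(
        theta,
        pi,
        focals_per_individual,
        rng,
        eta=eta,
        animal_ids=list(subjects),
        extra_truth={
            "alpha": alpha,
            "beta": beta,
            "u": u,
            "eps": eps,
            "settings": {
                "sigma2": sigma2.tolist(),
                "tau": tau,
                "gamma": gamma.tolist(),
            },
        },
    )
    return data, covs, A, truth
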