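"""Warm-starting the Gibbs sampler from a "flattened" mixture fit.

The posterior of the full model is highly multimodal; naive random starts
routinely land the sampler in poor local modes.  The remedy: first fit a
flattened version of the model that pretends all focal observations came
from a single animal — a plain K-component mixture of products of
categoricals (a naive-Bayes classifier) — by maximum likelihood with EM.
Starting points for EM are the single-state ML solution (empirical level
frequencies) perturbed with independent Gaussian noise on the log scale,
and the best of several such starts is kept.  Initial state assignments for
the Gibbs chain are then drawn from the flat fit's per-observation
membership probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import BinnedDataset
from .model import StateParams, loglik_matrix

__all__ = ["FlatModelFit", "fit_flat_model", "draw_initial_assignments"]


@dataclass
class FlatModelFit:
    theta: StateParams
    weights: np.ndarray  # (K,) mixture weights
    log_likelihood: float
    memberships: np.ndarray  # (N_obs, K) posterior membership probabilities

    def __post_init__(self):
        if not np.isfinite(self.log_likelihood):
            raise ValueError("flat-model log-likelihood must be finite")
        if not np.allclose(self.memberships.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("membership rows must sum to 1")


def _single_state_ml(data: BinnedDataset) -> np.ndarray:
    """Empirical level frequencies, padded to (1, B, Lmax)."""
    B = data.n_behaviors
    Lmax = int(data.n_levels.max())
    theta = np.zeros((1, B, Lmax))
    for b in range(B):
        c = data.level_counts[b].astype(float)
        theta[0, b, : len(c)] = c / c.sum()
    return theta


def _em(
    data: BinnedDataset,
    theta0: np.ndarray,
    weights0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    K, B, Lmax = theta0.shape
    lev = data.levels - 1
    n_obs = data.n_obs
    pad = np.arange(Lmax)[None, :] >= data.n_levels[:, None]  # (B, Lmax)

    theta = theta0.copy()
    w = weights0.copy()
    ll_prev = -np.inf
    for _ in range(max_iter):
        sp = StateParams(theta=theta, n_levels=data.n_levels)
        logp = loglik_matrix(data, sp) + np.log(w)[:, None]  # (K, N_obs)
        norm = logsumexp(logp, axis=0)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[None, :])  # (K, N_obs)

        w = resp.sum(axis=1) / n_obs
        w = np.clip(w, 1e-12, None)
        w /= w.sum()
        counts = np.zeros((K, B, Lmax))
        for b in range(B):
            # accumulate responsibilities by observed level of behavior b
            for l in range(int(data.n_levels[b])):
                mask = lev[:, b] == l
                if mask.any():
                    counts[:, b, l] = resp[:, mask].sum(axis=1)
        tot = counts.sum(axis=2, keepdims=True)
        theta = np.where(tot > 0, counts / np.where(tot > 0, tot, 1.0), theta)
        theta[:, pad] = 0.0
        theta /= theta.sum(axis=2, keepdims=True)

        if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and np.isfinite(ll_prev):
            ll_prev = ll
            break
        ll_prev = ll

    sp = StateParams(theta=theta, n_levels=data.n_levels)
    logp = loglik_matrix(data, sp) + np.log(w)[:, None]
    norm = logsumexp(logp, axis=0)
    resp = np.exp(logp - norm[None, :])
    return theta, w, float(norm.sum()), resp.T


def fit_flat_model(
    data: BinnedDataset,
    K: int,
    n_starts: int = 10,
    noise_scale: float = 0.5,
    rng: np.random.Generator | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> FlatModelFit:
    """ML fit of the K-component categorical mixture via multi-start EM.

    Each start perturbs the log of the single-state ML solution with
    independent N(0, noise_scale^2) noise per parameter; the start with the
    highest final log-likelihood wins.  ``K = 1`` returns the closed-form
    empirical-frequency solution.
    """
    rng = np.random.default_rng(rng)
    if K < 1 or n_starts < 1:
        raise ValueError("K and n_starts must be >= 1")
    n_distinct = len({tuple(r) for r in data.levels.tolist()})
    if K > n_distinct:
        import warnings

        warnings.warn(
            f"K={K} exceeds the {n_distinct} distinct observation rows; "
            "components may be degenerate",
            stacklevel=2,
        )

    base = _single_state_ml(data)
    pad = np.arange(base.shape[2])[None, :] >= data.n_levels[:, None]
    if K == 1:
        theta, w, ll, resp = _em(data, base, np.ones(1), max_iter=1, tol=tol)
        return FlatModelFit(
            theta=StateParams(theta=base, n_levels=data.n_levels),
            weights=np.ones(1),
            log_likelihood=ll,
            memberships=np.ones((data.n_obs, 1)),
        )

    best = None
    with np.errstate(divide="ignore"):
        log_base = np.log(np.clip(base[0], 1e-8, None))
    for _ in range(n_starts):
        logits = log_base[None, :, :] + rng.normal(
            0.0, noise_scale, size=(K,) + base.shape[1:]
        )
        logits[:, pad] = -np.inf
        theta0 = np.exp(logits - logsumexp(logits, axis=2, keepdims=True))
        theta0[:, pad] = 0.0
        theta, w, ll, resp = _em(data, theta0, np.full(K, 1.0 / K), max_iter, tol)
        if best is None or ll > best[2]:
            best = (theta, w, ll, resp)

    theta, w, ll, resp = best
    return FlatModelFit(
        theta=StateParams(theta=theta, n_levels=data.n_levels),
        weights=w,
        log_likelihood=ll,
        memberships=resp,
    )


def draw_initial_assignments(
    fit: FlatModelFit, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw z per observation from the flat fit's membership rows (0-based)."""
    rng = np.random.default_rng(rng)
    m = fit.memberships
    with np.errstate(divide="ignore"):
        logm = np.log(np.clip(m, 1e-300, None))
        logm[m == 0] = -np.inf
    return np.argmax(logm + rng.gumbel(size=m.shape), axis=1)


def initial_assignments(
    data: BinnedDataset,
    K: int,
    rng: np.random.Generator | None = None,
    n_starts: int = 10,
    noise_scale: float = 0.5,
    **em_kwargs,
) -> tuple[np.ndarray, FlatModelFit]:
    """Convenience wrapper: flat fit, then membership-sampled assignments."""
    rng = np.random.default_rng(rng)
    fit = fit_flat_model(
        data, K, n_starts=n_starts, noise_scale=noise_scale, rng=rng, **em_kwargs
    )
    return draw_initial_assignments(fit, rng), fit


__all__.append("initial_assignments")
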