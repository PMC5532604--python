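"""Post-sampling analyses: predictions, matching, recovery and heritability.

Everything here consumes ``PosteriorSamples`` and is computed per posterior
draw, so uncertainty propagates into every summary:

* covariate-profile phenotype prediction (random effects at zero);
* coefficients reported relative to a baseline state (the softmax layer has
  only K-1 identified contrasts);
* the pseudo-h2 statistic — out of the across-animal variance left
  unexplained by covariates alone, the share explained when additive
  genetic effects are added (can be negative when adding them hurts);
* greedy matching of fitted states to reference states by parameter-vector
  correlation, and per-individual phenotype recovery against a known truth;
* across-year repeatability of posterior-mean phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .model import StateParams, softmax
from .sampler import PosteriorSamples

__all__ = [
    "CovariateProfile",
    "PseudoH2Result",
    "StateMatching",
    "predict_phenotype",
    "baseline_relative_coefficients",
    "pseudo_h2",
    "greedy_state_match",
    "phenotype_recovery",
    "repeatability",
    "occupancy_order",
]


@dataclass(frozen=True)
class CovariateProfile:
    """Values for the fixed-effect design columns at which to predict.

    Unspecified columns default to 0, i.e. the population average on the
    centered/standardized design scale (the modal level for dummy-coded
    categorical columns when the mode is the reference level).
    """

    values: dict[str, float]

    def design_row(self, columns: list[str]) -> np.ndarray:
        unknown = [c for c in self.values if c not in columns]
        if unknown:
            raise KeyError(f"profile names unknown covariates: {unknown}")
        return np.array([float(self.values.get(c, 0.0)) for c in columns])


@dataclass
class PseudoH2Result:
    draws: np.ndarray  # (S, K), NaN where undefined for that draw
    mean: np.ndarray  # (K,)
    ci66: np.ndarray  # (2, K)
    ci95: np.ndarray  # (2, K)
    n_undefined: np.ndarray  # (K,)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": np.arange(1, len(self.mean) + 1),
                "mean": self.mean,
                "ci66_low": self.ci66[0],
                "ci66_high": self.ci66[1],
                "ci95_low": self.ci95[0],
                "ci95_high": self.ci95[1],
                "n_undefined_draws": self.n_undefined,
            }
        )


@dataclass
class StateMatching:
    """Injective map fitted-state -> reference-state with match correlations."""

    fitted_to_ref: dict[int, int]
    correlations: dict[int, float]
    unmatched_fitted: list[int]

    def matched_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.fitted_to_ref.items())


def occupancy_order(samples: PosteriorSamples, X: np.ndarray | None = None) -> np.ndarray:
    """Fitted states ordered by descending posterior-mean population occupancy."""
    pi = samples.pi_draws(X)  # (S, N, K)
    occ = pi.mean(axis=(0, 1))
    return np.argsort(-occ, kind="stable")


def predict_phenotype(
    profile: CovariateProfile,
    samples: PosteriorSamples,
    columns: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Posterior of the phenotype at a covariate profile.

    Per draw: eta_k = alpha_k + x' beta_k with random effects at zero, then
    softmax.  Returns the draws plus mean and central 66%/95% intervals.
    """
    columns = columns if columns is not None else samples.covariate_names
    x = profile.design_row(columns)
    if len(x) != samples.beta.shape[1]:
        raise ValueError("profile length does not match fitted design")
    eta = samples.alpha + (x @ samples.beta if x.size else 0.0)  # (S, K)
    pi = softmax(eta, axis=1)
    return {
        "draws": pi,
        "mean": pi.mean(axis=0),
        "ci66": np.quantile(pi, [0.17, 0.83], axis=0),
        "ci95": np.quantile(pi, [0.025, 0.975], axis=0),
    }


def baseline_relative_coefficients(
    samples: PosteriorSamples, baseline: int
) -> pd.DataFrame:
    """Posterior summaries of alpha_k - alpha_base and beta_k - beta_base.

    ``baseline`` is a 0-based state index.  The baseline state's own
    contrasts are identically zero and are omitted.
    """
    K = samples.n_states
    if not 0 <= baseline < K:
        raise ValueError("baseline state out of range")
    rows = []
    d_alpha = samples.alpha - samples.alpha[:, baseline][:, None]  # (S, K)
    d_beta = samples.beta - samples.beta[:, :, baseline][:, :, None]  # (S, P, K)
    names = samples.covariate_names or [
        f"x{j}" for j in range(samples.beta.shape[1])
    ]
    for k in range(K):
        if k == baseline:
            continue
        terms = [("(intercept)", d_alpha[:, k])] + [
            (names[p], d_beta[:, p, k]) for p in range(samples.beta.shape[1])
        ]
        for name, dr in terms:
            lo, hi = np.quantile(dr, [0.025, 0.975])
            rows.append(
                {
                    "state": k,
                    "term": name,
                    "mean": dr.mean(),
                    "ci95_low": lo,
                    "ci95_high": hi,
                }
            )
    return pd.DataFrame(rows)


def pseudo_h2(samples: PosteriorSamples, X: np.ndarray | None) -> PseudoH2Result:
    """Pseudo-h2 per state: 1 - var(pi - pi_hat(u)) / var(pi - pi_hat(B)).

    pi is the full phenotype (with individual effects), pi_hat(B) the
    prediction from covariates alone, pi_hat(u) from covariates plus genetic
    effects; variances are across animals, computed per posterior draw.
    Draws with zero residual variance under the covariate-only prediction
    are undefined and excluded with a warning.
    """
    if samples.u is None:
        raise ValueError("model was fitted without a genetic component")
    S = samples.n_draws
    K = samples.n_states
    out = np.full((S, K), np.nan)
    for s in range(S):
        xb = (X @ samples.beta[s]) if (X is not None and samples.beta.shape[1]) else 0.0
        eta_b = samples.alpha[s][None, :] + xb
        eta_u = eta_b + samples.u[s]
        eta_full = eta_u + samples.eps[s]
        pi = softmax(eta_full, axis=1)
        pi_b = softmax(np.broadcast_to(eta_b, pi.shape), axis=1)
        pi_u = softmax(eta_u, axis=1)
        denom = np.var(pi - pi_b, axis=0)
        numer = np.var(pi - pi_u, axis=0)
        ok = denom > 0
        out[s, ok] = 1.0 - numer[ok] / denom[ok]
    n_undef = np.isnan(out).sum(axis=0)
    if n_undef.any():
        warn(
            f"pseudo-h2 undefined in {int(n_undef.sum())} draw/state cells "
            "(zero covariate-residual variance); excluded",
            stacklevel=2,
        )
    mean = np.nanmean(out, axis=0)
    ci66 = np.nanquantile(out, [0.17, 0.83], axis=0)
    ci95 = np.nanquantile(out, [0.025, 0.975], axis=0)
    return PseudoH2Result(draws=out, mean=mean, ci66=ci66, ci95=ci95, n_undefined=n_undef)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def greedy_state_match(
    fitted_theta: StateParams,
    reference_theta: StateParams,
    fitted_order: np.ndarray | None = None,
) -> StateMatching:
    """Greedily match fitted states to reference states.

    Iterating over fitted states (default order: as given; pass the
    occupancy order for the reporting convention), each is matched to the
    not-yet-matched reference state whose concatenated parameter vector has
    the highest Pearson correlation with it.  Surplus fitted states beyond
    the number of reference states remain unmatched.
    """
    F = fitted_theta.flatten_valid()
    R = reference_theta.flatten_valid()
    Kf, Kr = F.shape[0], R.shape[0]
    order = np.arange(Kf) if fitted_order is None else np.asarray(fitted_order)
    available = set(range(Kr))
    mapping: dict[int, int] = {}
    corrs: dict[int, float] = {}
    unmatched = []
    for kf in order:
        if not available:
            unmatched.append(int(kf))
            continue
        cand = sorted(available)
        cs = np.array([_corr(F[kf], R[kr]) for kr in cand])
        j = int(np.nanargmax(cs))
        mapping[int(kf)] = cand[j]
        corrs[int(kf)] = float(cs[j])
        available.discard(cand[j])
    return StateMatching(
        fitted_to_ref=mapping, correlations=corrs, unmatched_fitted=unmatched
    )


def phenotype_recovery(
    matching: StateMatching,
    true_pi: np.ndarray,
    fitted_pi_mean: np.ndarray,
) -> np.ndarray:
    """Per-individual Pearson correlation of true vs matched fitted phenotypes.

    For each animal, the true probabilities of the matched reference states
    are correlated with the fitted posterior-mean probabilities of the
    corresponding fitted states.  Constant vectors give NaN.
    """
    pairs = matching.matched_pairs()
    if not pairs:
        raise ValueError("matching contains no matched pairs")
    kf = np.array([p[0] for p in pairs])
    kr = np.array([p[1] for p in pairs])
    true_pi = np.asarray(true_pi, dtype=float)
    fitted = np.asarray(fitted_pi_mean, dtype=float)
    return np.array(
        [_corr(true_pi[i, kr], fitted[i, kf]) for i in range(true_pi.shape[0])]
    )


def repeatability(pi_year1: np.ndarray, pi_year2: np.ndarray) -> np.ndarray:
    """Per-state Pearson correlation across animals of posterior-mean
    phenotypes measured in two periods (same animals, same states)."""
    pi1 = np.asarray(pi_year1, dtype=float)
    pi2 = np.asarray(pi_year2, dtype=float)
    if pi1.shape != pi2.shape:
        raise ValueError("the two phenotype matrices must have the same shape")
    if pi1.shape[0] < 3:
        raise ValueError("repeatability needs at least 3 animals")
    return np.array([_corr(pi1[:, k], pi2[:, k]) for k in range(pi1.shape[1])])
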