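# Methods

## Model

A focal observation is represented as a vector of ordered levels, one per
behavior of the ethogram. The generative model has three layers.

**Observation layer.** Each focal observation carries one latent behavioral
state; given the state, behaviors are independent categoricals over their
levels (`θ^{(k,b)}`, a probability vector per state × behavior). A state is
therefore not a point pattern but a joint distribution over behavior
amounts, which lets one state pin a behavior precisely while being
indifferent about another. Confining a whole 10-minute focal to a single
state is a deliberate simplification: within-focal state switching is not
modeled (rare behaviors make switches nearly undetectable anyway, and the
restriction keeps inference tractable).

**Phenotype layer.** Animal `i`'s state probabilities π_i are the softmax of
propensities η_{i,k} = α_k + X_i'β_k + u_{i,k} + ε_{i,k}. All K propensities
are retained even though only K−1 contrasts are identified; the priors
provide soft identification, and baseline subtraction happens only in
reporting (`baseline_relative_coefficients`). This mirrors how the sampler
treats the layer and avoids privileging one state during inference.

**Random effects and priors.** ε_{i,k} ~ N(0, σ²_k), α_k ~ N(0, τσ²_k),
u_{·,k} ~ N(0, γ_k σ²_k A) with A = 2 × kinship. Sharing the scale σ²_k
across the three components makes every conditional conjugate. Hyperpriors:
Dirichlet(1) on each θ table, N(0,1) on β (which presumes standardized
covariates — the design builder centers/scales numeric covariates by
default), InvGamma(0.005, 0.0005) on σ²_k and τ, and InvGamma(0.165,
0.0165) on γ_k. The γ prior is deliberately not the "uninformative" choice:
it is picked so that the implied prior on approximate heritability
γ/(1+γ) is heavy in *both* tails (≈23% of mass below 0.1 and ≈38% above
0.9 by simulation), rather than piling mass near 1.

## Sampler

Per iteration: conjugate Dirichlet draw of θ given z; categorical draw of z
given (θ, π) in log space with Gumbel-max sampling; then per state the
regression block; then variance components.

The multinomial-logit layer is handled by Pólya-Gamma augmentation in
one-vs-rest form: holding the other states' propensities fixed in an offset
C_i = log Σ_{k'≠k} exp(η_{i,k'}), the likelihood in ψ_i = η_{i,k} − C_i is
a binomial logit with n_{i,k} successes in n_i trials, so ω_i ~ PG(n_i, ψ_i)
renders (α_k, β_k, u_{·,k}, ε_{·,k}) jointly Gaussian. The whole block is
drawn in one Cholesky solve per state — the "partial collapse" — which
mixes dramatically better than component-wise updates because α, u and ε
are strongly coupled through the likelihood. The prior precision of the
u-block uses A⁻¹ computed once from a jittered (default 1e-8) Cholesky
factorization. With a single state (K = 1) the layer carries no information
(π ≡ 1) and the block draw reduces to the prior.

The PG(b, c) sampler is implemented in-package (numba-compiled Devroye
rejection sampling for PG(1, c); integer b by convolution) and validated
against the closed-form moments E[ω] = (b/2c)·tanh(c/2) and
Var[ω] = b(sinh c − c)/(4c³ cosh²(c/2)).

Correctness of the full sampler is established by a Geweke-style
joint-distribution test: alternating one Gibbs parameter scan with
re-simulation of the data given (z, θ) must leave every parameter's marginal
equal to its prior. The test instance uses proper, moderately informative
inverse-gamma test priors (shape 3, rate 3) because the default
near-improper priors make the successive-conditional chain numerically
explosive; the validity of the conditionals does not depend on the prior
constants. Draws are thinned (every 20th of 100,000) because the KS
comparison assumes independent samples.

**Update order** is θ → z → regression block → variances; any fixed scan
order is valid, and starting with θ lets the informed initial assignments
shape the first state draw. **Thinning** keeps `thin_to` evenly spaced
draws per chain, discarding the first `burn_in_kept` kept draws. **Label
switching** is not corrected within chains — the informed initialization
makes it rare — and all truth/cross-run comparisons go through greedy state
matching. **Reproducibility**: chain c uses seed + c; the PG kernel is
seeded from the chain's generator on every call.

## Initialization

The flat model (all observations pooled into one pseudo-animal — a
naive-Bayes mixture) is fitted by multi-start EM: starts are the
single-state ML solution (empirical level frequencies) perturbed by
N(0, 0.5²) noise on log-probabilities, default 10 starts, tolerance 1e-6
relative log-likelihood, max 500 iterations. Initial z is drawn from the
best fit's membership probabilities. The regression layer starts at α =
centered log mixture weights, β = 0, u = ε = 0, unit variances (the default
variance hyperpriors have undefined means, so "prior mean" is not
available as an initial value).

## Model selection

WAIC is computed pointwise over focal observations with the z-marginalized
likelihood p(y_f | π_i, θ) = Σ_k π_{i,k} p(y_f | θ^{(k)}) — invariant to
state relabeling — and the variance-form penalty (pWAIC2):
waic = −2(lppd − p_waic). Selection runs exclude the genetic component by
default (a flag includes it); heritability is estimated afterwards at the
chosen K.

A caveat that matters in practice: for mixtures (singular models) the
pointwise-variance penalty undercounts the optimism of a state that splits
an existing state to absorb sampling noise. On data simulated from an exact
K-state truth we observe WAIC curves that drop steeply up to the true K and
then go essentially flat, sometimes with the argmin one or two states above
the truth by a few hundredths of a percent — even though the true held-out
predictive density (computable in simulation) is best exactly at the
generating K. Alternative pointwise units (per animal), conditional-on-z
likelihoods, and phenotype-marginalized ("marginal WAIC") variants were
evaluated and do not change this; nor does the choice of EM versus
gradient-based warm starts. The practical recommendation printed in the
selection example is to read the WAIC table as "the smallest K on the
plateau" rather than the literal argmin.

## Synthetic data

The basic generator draws state tables by softmax-transforming i.i.d.
N(0, 1) level propensities, and phenotypes via η_{i,k} ~ N(α_k, 0.0625),
α_k ~ N(0, 0.25) — second arguments read as **variances**, consistent with
the random-effect layer's notation. Defaults: 200 individuals × 100
focals, 30 behaviors, 3 levels. The extended generator composes the full
regression layer (covariates: one binary + standardized continuous by
default, β ~ N(0,1); pedigree simulated by forward random mating with
optional full-sib litters; u via Cholesky of A) for genetic-recovery
studies.

What the generator emulates: the dimensionality, zero-inflation-like level
structure, and hierarchical phenotype variation of real focal data. What it
does not: temporal structure within and between focals, observer effects,
unbalanced observation counts, behavior semantics (grooming bouts, reciprocity),
or covariate-relatedness confounding. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Binning

Cutpoints are the 1st, 20th, 40th, 60th, 80th and 99th percentiles of each
behavior's column, computed with the "lower" (data-value) quantile
convention; duplicates are collapsed and cutpoints at or above the column
maximum are dropped, so a zero-inflated count behavior collapses to levels
{0, 1, >1} and a constant column to a single level. Interpolating quantile
conventions are available but manufacture fractional cutpoints between tied
counts, creating definitionally empty bins — hence the data-value default.
Values equal to a cutpoint fall in the lower bin. The scheme is fitted on
the full dataset before modeling (no train/test split), matching how the
binning is meant to standardize a single study's data. Event and activity
behaviors share the pipeline.

## Numerical choices

- All categorical sampling is Gumbel-max in log space; softmax is
  max-shifted.
- Dirichlet draws use gamma variates; a level with shape 0 (padding) draws
  exactly 0.
- PG draws for animals with zero observations are clamped to 1e-12 so the
  block precision stays positive definite; the corresponding pseudo-data
  contribute nothing.
- A⁻¹ is obtained from a jittered Cholesky once per fit; quadratic forms
  u'A⁻¹u reuse it.
- pseudo-h² draws with zero covariate-residual variance are recorded as
  undefined (NaN) and excluded with a warning.
- Greedy state matching iterates fitted states in a caller-supplied order;
  reporting uses descending posterior-mean occupancy, since greedy results
  are order-dependent. Matching correlates concatenated valid θ entries
  (Pearson).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| K | user/WAIC | number of behavioral states |
| n_iterations / thin_to / burn_in_kept | 100000 / 1000 / 100 | production chain settings; tests and examples use far smaller values |
| n_chains | 2 | independent chains, seeds seed+c |
| n_starts / init noise | 10 / 0.5 | EM multi-start warm start |
| jitter | 1e-8 | diagonal regularization of A |
| percentiles | 1,20,40,60,80,99 | binning cutpoints (≤7 levels) |
| Hyperpriors | see above | Dirichlet/normal/inverse-gamma constants |

## Known limitations

- One state per focal observation; no within-focal dynamics.
- Categorical likelihood only (the seam for Poisson/truncated-normal
  alternatives exists at `loglik_matrix` but is not implemented).
- WAIC's argmin can sit slightly above the true K (see Model selection).
- Repeatability across years is supported by duplicating animals with
  year-specific identities (no extra hierarchy level), without a genetic
  component; population-level inferences should not be drawn from such
  artificially inflated runs.
- No genetic groups for unknown parents; missing parents are founders.
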