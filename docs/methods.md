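# Methods

## Model

`stcarlocal` fits a Bayesian spatio-temporal *localized* conditional
autoregressive (CAR) model to area-time disease counts. For area
i = 1..N and time j = 1..J,

    y_ij ~ Poisson(E_ij * theta_ij)
    log theta_ij = x_ij' beta + u_ij + lambda_{Z_ij}

where `E_ij` is the expected count under the overall study-wide rate
(`E_ij = (sum y / sum n) * n_ij`, so `sum E = sum y` exactly) and
`theta_ij` is the relative risk. The latent surface is deliberately split
into two components with opposite jobs:

* **u** — a smooth spatio-temporal Gaussian Markov random field. The first
  time slice follows the intrinsic CAR (ICAR) distribution with precision
  `Q = D - W` scaled by `1/tau2` (`W` the binary adjacency, `D` its degree
  diagonal; spatial dependence fixed at 1). Later slices follow
  `u_j | u_{j-1} ~ N(rhoT * u_{j-1}, tau2 * Q^-)`, an AR(1) in time. `Q` is
  singular (rank N-1 on a connected graph); identifiability is handled by
  re-centering `u` to zero total sum after every sweep and by using rank
  N-1 in the variance update.
* **lambda_Z** — a piecewise-constant cluster intercept. Each cell carries
  a label `Z_ij` in {1..G}; the ordered intercepts
  `lambda_1 < ... < lambda_G` let spatially or temporally adjacent cells sit
  in *different* risk groups, capturing discontinuities the smooth field
  would blur. Labels are shrunk towards the middle group
  `G* = (G+1)/2` (odd G) or `G/2` (even G — implemented exactly as stated
  in the original formulation, although it biases labels below the median)
  and towards their previous-time value through

      f(Z_ij | Z_i,j-1) ∝ exp(-delta [(Z_ij - Z_i,j-1)^2 + (Z_ij - G*)^2])

  with the first time point penalized by the `G*` term alone.

Priors: `lambda_k ~ U(lambda_{k-1}, lambda_{k+1})` (order statistics,
`lambda_0 = -inf`, `lambda_{G+1} = +inf`); `delta ~ U(1, 100)`;
`tau2 ~ Inverse-Gamma(a, b)` with (1, 0.01) as default and five standard
settings for sensitivity analysis; `rhoT ~ U(0, 1)`;
`beta ~ N(0, 1e5 I)`. No separate global intercept is sampled: it is not
identifiable alongside the G cluster intercepts, so the overall level is
absorbed by the lambdas; the reported "overall level" is the posterior
mean of `lambda_{Z_ij}` averaged over cells.

## Estimation

Single-chain Metropolis-within-Gibbs with the fixed sweep
(u, tau2, rhoT, beta, lambda, Z, delta):

* `u`: single-site random-walk Metropolis, vectorized over conditionally
  independent colour classes of the adjacency graph, one time slice at a
  time; the prior term combines the quadratic forms of slices j-1, j, j+1
  through the AR(1) structure.
* `tau2`: conjugate Gibbs,
  `IG(a + (N-1) J / 2, b + quad(u)/2)`.
* `rhoT`: random-walk Metropolis on (0, 1) against the transition density
  of `u_2..u_J` (not updated when J = 1, where it is unidentified).
* `beta`: joint spherical random-walk Metropolis.
* `lambda`: per-component random-walk Metropolis; proposals outside
  `(lambda_{k-1}, lambda_{k+1})` are rejected, so the ordering holds by
  construction. A component with no assigned cells performs a free
  in-interval random walk, as the order prior implies.
* `Z`: exact categorical full conditional per cell,
  `∝ Poisson(y | E theta(r)) f(r | Z_prev) f(Z_next | r)`, swept slice by
  slice, vectorized over areas.
* `delta`: random-walk Metropolis against the product of penalty-process
  label probabilities over all cells.

Step sizes are adapted on the log scale during burn-in only (targets:
45% acceptance for scalar blocks, 30% for vector blocks) and frozen
afterwards, so the retained chain satisfies detailed balance.

### Interweaving moves

The blocks above mix the *fit* quickly but the *decomposition* slowly:
the likelihood constrains only `x'beta + u + lambda_Z`, so the chain must
travel along likelihood-flat ridges where one component trades off
against another. Plain single-site updates diffuse along these ridges at
a rate set by the per-cell posterior width — with informative counts,
thousands of iterations per effective draw (an effect visible in
published applications of this model family, which report effective
sample sizes near 1 for regression coefficients). Three
likelihood-preserving Metropolis moves are therefore interleaved, each an
exact move on the same posterior:

1. `beta' = beta + e`, `u' = u - X e` (covariates centered): a
   unit-Jacobian shear whose acceptance involves only the field and beta
   priors.
2. `lambda_k' = lambda_k + d`, `u' = u - d` on cells labelled k, with the
   released overall mean transferred to a common shift of all lambdas.
3. per-cell label steps `Z_ij -> Z_ij +- 1` with
   `u_ij' = u_ij + lambda_old - lambda_new`, accepted against the field
   prior and the penalty process; this unsticks label configurations the
   exact conditional leaves metastable once `u` has absorbed a cluster
   jump.

With these moves, coefficient effective sample sizes on the default
synthetic problem rise from single digits to several hundred per 2,000
stored draws.

### Parameterization and initialization

Sampling internally uses mean-centered covariates; the level `x̄'beta` is
absorbed by the cluster intercepts during sampling and shifted back at
storage time, so stored chains satisfy
`theta_ij = exp(x_ij' beta + u_ij + lambda_{Z_ij})` exactly on the raw
covariate scale. Covariates are *not* standardized by default: reported
coefficients are per raw unit (e.g. per percentage point of poverty).

Initialization: `beta` at the least-squares fit of the empirical log-risk
`log((y + 0.5)/E)` on the centered covariates (a GLM-style start; the
posterior for beta is orders of magnitude narrower than the prior, and a
random walk started at zero would spend most of a short chain in
transit); `lambda` at equally spaced quantiles of the residual log-risk;
`Z` at the nearest initial intercept (a kmeans-style assignment — starting
all labels at `G*` leaves chains metastable, with `u` absorbing the
cluster jumps, emptied groups drifting along their flat order prior, and
`tau2` inflated); `u = 0`; `tau2` at the prior mode `b/(a+1)`;
`rhoT = 0.5`; `delta` at its lower bound.

MCMC defaults: 22,000 iterations, 2,000 burn-in, thinning 10 (2,000
stored draws). A single seeded generator drives all randomness; identical
seeds give bit-identical chains.

### Prior-only mode

`ModelConfig(prior_only=True)` makes every block target its own marginal
prior (for `tau2` and `rhoT` this also removes the latent-field terms;
otherwise they would target the field's conditional rather than
`IG(a, b)` and `U(0, 1)`). Used to verify that the Metropolis machinery
reproduces `delta ~ U(1,100)`, `rhoT ~ U(0,1)`, `tau2 ~ IG(a,b)` and
`beta ~ N(0, v)`. Because all five standard IG settings have shape <= 1,
the tau2 check uses the always-finite precision moments
(`E[1/tau2] = a/b`) rather than the nonexistent scale mean.

## Model comparison

* **DIC** = `Dbar + pD` with `pD = Dbar - D(thetabar)`; the plug-in
  deviance is evaluated at the per-cell posterior mean of `theta` (the
  fitted-value parameterization usual in disease mapping).
* **WAIC** = `-2 lppd + 2 pWAIC` with the variance-form penalty
  (`pWAIC = sum_cells var_s log p(y | theta^(s))`); pointwise densities are
  combined by log-sum-exp.
* **ESS**: `n / (1 + 2 sum rho_k)` with Geyer's initial-positive-sequence
  truncation of FFT-estimated autocorrelations; constant chains report 0
  with a warning.
* **Convergence triage**: the Geweke z-score (first 10% vs last 50%,
  spectral variances) on every monitored scalar (deviance, betas, lambdas,
  hyperparameters), with |z| < 2 for all of them required for the
  `converged` flag. Individual `u_ij`/`Z_ij` cells are not monitored by
  default.
* **Grid runner**: every subset of the covariate pool (2^p including the
  empty set) crossed with the cluster-count list and the hyperprior list;
  each fit gets seed `base_seed + row_index`; failures are recorded as
  failed rows without stopping the grid. The canonical protocol
  (G in {2,3,5}, five IG priors, five covariates) yields exactly
  480 = 3 x 5 x 32 rows. DIC and WAIC rankings are both reported; the
  package does not adjudicate between them.

A practical note on what DIC can resolve: with a free per-cell field,
covariate signal can be absorbed into `u` at a cost that shrinks as
counts grow, so DIC differences between covariate subsets are largest in
moderate-count regimes; with very large counts the criteria converge for
all subsets that fit equally well.

## Synthetic data

`simulate_dataset` draws every latent quantity from the model itself:
labels from the penalty process at `delta_true`, the field from
ICAR + AR(1) innovations (sampled in the positive eigenspace of `Q`, so
each innovation sums to zero exactly), covariates uniform on raw
percentage-style ranges, at-risk totals log-normal (matching the strong
right skew of real province-level denominators), counts Poisson. The
returned panel has its expected counts re-derived from the simulated
totals, so fitting never sees the generating baseline rate.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| lattice | 6 x 6 (N = 36) | desk-scale stand-in for a ~34-province panel |
| J | 3 | a three-year annual panel |
| beta_true | (0.02, 0.04) | the published coefficient regime per raw percentage point |
| lambda_true | (-1, 0, 1) | inter-cluster log-risk gaps of 1.0, inside the published range (0.48-3.9); smaller gaps (~0.5) make the decomposition genuinely unidentifiable — the posterior prefers absorbing the jumps into u and coverage of tau2 fails for any sampler |
| tau2_true | 0.1 | matches published posterior scale of the field variance |
| rhoT_true | 0.5 | mid-range temporal persistence |
| delta_true | 1.0 | published posterior sits at the lower bound of U(1,100) |
| n_mean | 50,000 | denominators in the tens of thousands, log-normal spread 0.5 |
| baseline_rate | 0.10 | a realistic overall prevalence |

What the generator does **not** emulate: irregular real adjacency
structures (a lattice is used unless a graph is supplied), covariate
spatial autocorrelation (covariates are white across cells), reporting
artefacts, and non-Poisson overdispersion. Passing tests therefore show
the machinery is correct under the model's own assumptions, not that the
model is adequate for any particular real dataset.

## Validation studies

* **Exhaustive enumeration**: on a 2-area, 2-time, 2-group instance the
  sampled per-cell label marginals match brute-force enumeration over all
  16 joint configurations to < 0.02 total variation.
* **Prior recovery**: likelihood disabled, the chains reproduce each
  prior's moments (delta mean 50.5, rhoT mean 0.5, IG precision moments).
* **Coverage**: 20 replicated 6x6x3 panels, G = 3, 22k iterations each —
  95% credible intervals cover the generating beta, tau2 and rhoT in at
  least 90% of replicates, and posterior-mean intercepts are always
  correctly ordered. Problem sizes are chosen so the full study runs in
  minutes on a single core.

## Numerical choices and edge cases

* Overflowing linear predictors in label updates are handled in log space
  (an infinite mean yields zero weight, never NaN).
* Modal-label ties break towards the smaller label; ranking ties break
  alphabetically by area label.
* The significance rule treats credible intervals as closed: a boundary
  exactly at zero counts as containing it.
* `spearman_screen` removes covariates greedily (most super-threshold
  pairs; ties to the larger maximum |rho|, then the larger column index)
  with a default threshold of 0.5, which reproduces the published
  screening count (5 of 7 covariates kept) on correlation structures like
  the published one; constant covariates are excluded up front since rank
  correlation is undefined for them.
* `J = 1` degenerates to a purely spatial localized model (`rhoT` is
  reported but never updated); provided for testing.
* Asymmetric adjacency input is symmetrized with a warning; islands are
  rejected (the ICAR prior is undefined for them); disconnected graphs
  warn.

## Known limitations

* Single chain; between-chain diagnostics (R-hat) are out of scope, as are
  alternative spatio-temporal CAR families and estimation of the spatial
  dependence parameter (fixed at 1).
* The exceedance probability Pr(theta > 1) is an extension beyond the
  published outputs of this model family, included because it is standard
  in disease mapping.
* With weak cluster separation the label/field decomposition is only
  prior-identified; posterior summaries of tau2 and the labels should be
  read with that in mind (the risk surface theta itself remains well
  identified).
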