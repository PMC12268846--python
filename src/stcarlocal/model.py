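"""Spatio-temporal localized CAR model and its Metropolis-within-Gibbs sampler.

The model for counts y_ij in area i (i = 1..N) and time j (j = 1..J) is

    y_ij ~ Poisson(E_ij * theta_ij)
    log theta_ij = x_ij' beta + psi_ij,      psi_ij = u_ij + lambda_{Z_ij}

with E_ij the expected count offset.  The latent surface has two pieces:

* ``u_ij`` -- a spatio-temporally smooth Gaussian Markov random field.  The
  first time slice follows an intrinsic CAR (ICAR) distribution with
  precision Q = D - W scaled by 1/tau2; later slices follow an AR(1)
  transition u_j | u_{j-1} ~ N(rho_T u_{j-1}, tau2 Q^-).  The spatial
  dependence parameter is fixed at 1 (pure ICAR smoothing), so step changes
  in risk are carried by the cluster component, not by u.
* ``lambda_{Z_ij}`` -- a piecewise-constant cluster intercept.  Each cell
  carries a label Z_ij in {1..G}; the ordered intercepts
  lambda_1 < ... < lambda_G follow the uniform order prior
  lambda_k ~ U(lambda_{k-1}, lambda_{k+1}).  Labels are shrunk towards the
  middle label G* and towards their previous-time value through a penalty
  process with strength delta (see :func:`penalty_probs`).

Hyperpriors: tau2 ~ Inverse-Gamma(a, b); rho_T ~ Uniform(0, 1);
delta ~ Uniform(L_delta, U_delta); beta ~ N(0, v I).

No separate global intercept is sampled: it is not identifiable alongside
the G cluster intercepts, so the overall level is absorbed by the lambdas.

Estimation is single-chain Metropolis-within-Gibbs with the fixed block
sweep (u, tau2, rho_T, beta, lambda, Z, delta).  Random-walk step sizes are
adapted during burn-in only and frozen afterwards, preserving detailed
balance for the retained samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import gammaln

from .dataio import AdjacencyGraph, StudyFrame, ValidationError

__all__ = [
    "ModelConfig",
    "MCMCState",
    "PosteriorSamples",
    "penalty_probs",
    "middle_label",
    "log_poisson_loglik",
    "update_Z",
    "update_lambda",
    "update_delta",
    "update_u",
    "update_tau2",
    "update_rhoT",
    "update_beta",
    "run_mcmc",
]


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Model and MCMC settings.

    Parameters
    ----------
    G : int
        Number of ordered cluster intercepts (>= 1).  Small odd values
        (3, 5) are the usual choice; 2 is also supported.
    tau2_prior : (a, b)
        Inverse-Gamma shape/scale for the random-effect variance tau2.
        Default (1, 0.01), a weakly informative disease-mapping standard.
    delta_bounds : (L, U)
        Support of the uniform prior on the label penalty delta;
        default (1, 100).
    beta_prior_var : float
        Prior variance v of each regression coefficient, beta ~ N(0, v I).
        Default 1e5 (weakly informative on the log-risk scale).
    n_iter, burnin, thin : int
        Chain length, discarded prefix, thinning stride.
    prior_only : bool
        Diagnostic mode: every block targets its own prior (the data
        likelihood and cross-level terms are switched off) so the chain
        should reproduce delta ~ U(L, U), rho_T ~ U(0, 1),
        tau2 ~ IG(a, b) and beta ~ N(0, v).  u and Z are then held fixed
        except that Z still follows its penalty process.
    """

    G: int = 3
    tau2_prior: tuple[float, float] = (1.0, 0.01)
    delta_bounds: tuple[float, float] = (1.0, 100.0)
    rho_s: float = 1.0  # fixed: intrinsic CAR
    beta_prior_var: float = 1e5
    n_iter: int = 22_000
    burnin: int = 2_000
    thin: int = 10
    seed: int = 0
    adapt_interval: int = 50
    target_accept_scalar: float = 0.45
    target_accept_vector: float = 0.30
    prior_only: bool = False
    step_u: float = 0.1
    step_lambda: float = 0.05
    step_delta: float = 20.0
    step_rhoT: float = 0.2
    step_beta: float = 0.01

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValidationError("G must be >= 1")
        L, U = self.delta_bounds
        if not L < U:
            raise ValidationError("delta bounds must satisfy L < U")
        if not self.n_iter > self.burnin >= 0:
            raise ValidationError("need n_iter > burnin >= 0")
        if self.rho_s != 1.0:
            raise ValidationError("only the intrinsic CAR (rho_s = 1) is supported")


@dataclass
class MCMCState:
    """One point in the parameter space of the localized CAR model."""

    beta: np.ndarray          # (p,)
    lam: np.ndarray           # (G,) strictly increasing
    Z: np.ndarray             # (N, J) int labels in 1..G
    delta: float
    u: np.ndarray             # (N, J)
    tau2: float
    rhoT: float

    def copy(self) -> "MCMCState":
        return MCMCState(
            self.beta.copy(), self.lam.copy(), self.Z.copy(),
            self.delta, self.u.copy(), self.tau2, self.rhoT,
        )

    def validate(self, config: ModelConfig) -> None:
        if np.any(np.diff(self.lam) <= 0):
            raise ValidationError("lambda must be strictly increasing")
        if self.Z.min() < 1 or self.Z.max() > config.G:
            raise ValidationError("Z labels out of range")
        L, U = config.delta_bounds
        if not L <= self.delta <= U:
            raise ValidationError("delta out of bounds")
        if self.tau2 <= 0:
            raise ValidationError("tau2 must be positive")

    def log_theta(self, frame: StudyFrame) -> np.ndarray:
        xb = frame.X @ self.beta if self.beta.size else 0.0
        return xb + self.u + self.lam[self.Z - 1]


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in chains of every model quantity.

    ``theta`` holds the fitted relative-risk chain per cell; scalar chains
    are 1-D arrays of length S = (n_iter - burnin) / thin.
    """

    beta: np.ndarray          # (S, p)
    lam: np.ndarray           # (S, G)
    Z: np.ndarray             # (S, N, J) int8
    delta: np.ndarray         # (S,)
    u: np.ndarray             # (S, N, J)
    tau2: np.ndarray          # (S,)
    rhoT: np.ndarray          # (S,)
    theta: np.ndarray         # (S, N, J)
    acceptance: dict[str, float]
    config: ModelConfig
    area_ids: list[str]
    time_ids: list[str]
    covariates: list[str]

    @property
    def S(self) -> int:
        return self.delta.shape[0]

    def scalar_chains(self) -> dict[str, np.ndarray]:
        """Monitored scalar chains keyed by name (betas, lambdas, hyperparameters)."""
        out: dict[str, np.ndarray] = {}
        for c, nm in enumerate(self.covariates):
            out[f"beta_{nm}"] = self.beta[:, c]
        for k in range(self.lam.shape[1]):
            out[f"lambda{k + 1}"] = self.lam[:, k]
        out["delta"] = self.delta
        out["tau2"] = self.tau2
        if len(self.time_ids) > 1:
            out["rhoT"] = self.rhoT
        return out

    def save(self, out_dir: str | Path) -> None:
        """Write chains as CSV plus a JSON config echo."""
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.scalar_chains()).to_csv(out / "scalars.csv", index=False)
        cells = [f"{a}|{t}" for a in self.area_ids for t in self.time_ids]
        pd.DataFrame(
            self.theta.reshape(self.S, -1), columns=cells
        ).to_csv(out / "theta.csv", index=False)
        pd.DataFrame(
            self.Z.reshape(self.S, -1), columns=cells
        ).to_csv(out / "z.csv", index=False)
        pd.DataFrame(
            self.u.reshape(self.S, -1), columns=cells
        ).to_csv(out / "u.csv", index=False)
        meta = asdict(self.config)
        meta.update(
            acceptance=self.acceptance,
            area_ids=self.area_ids,
            time_ids=self.time_ids,
            covariates=self.covariates,
        )
        (out / "fit.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# penalty process on cluster labels
# ---------------------------------------------------------------------------

def middle_label(G: int) -> int:
    """The label G* towards which the penalty shrinks: (G+1)/2 for odd G, G/2 for even."""
    return (G + 1) // 2 if G % 2 == 1 else G // 2


def penalty_probs(z_prev: int | None, delta: float, G: int) -> np.ndarray:
    """Prior label probabilities under the temporal Markov penalty.

    For the first time point (``z_prev is None``) label r has probability
    proportional to exp(-delta (r - G*)^2); thereafter proportional to
    exp(-delta [(r - z_prev)^2 + (r - G*)^2]).  Larger delta shrinks labels
    harder towards the middle label G* and towards temporal persistence.
    """
    if G < 1:
        raise ValidationError("G must be >= 1")
    r = np.arange(1, G + 1, dtype=float)
    gstar = middle_label(G)
    pen = (r - gstar) ** 2
    if z_prev is not None:
        pen = pen + (r - z_prev) ** 2
    logp = -delta * pen
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def _penalty_matrix(delta: float, G: int) -> np.ndarray:
    """Row a = penalty_probs(z_prev=a+1, delta, G); shape (G, G)."""
    r = np.arange(1, G + 1, dtype=float)
    pen = (r[None, :] - r[:, None]) ** 2 + (r[None, :] - middle_label(G)) ** 2
    logp = -delta * pen
    logp -= logp.max(axis=1, keepdims=True)
    M = np.exp(logp)
    return M / M.sum(axis=1, keepdims=True)


def _log_penalty_chain(Z: np.ndarray, delta: float, G: int) -> float:
    """Joint log prior of all label sequences under the penalty process."""
    p0 = np.log(penalty_probs(None, delta, G))
    M = np.log(_penalty_matrix(delta, G))
    total = p0[Z[:, 0] - 1].sum()
    if Z.shape[1] > 1:
        total += M[Z[:, :-1] - 1, Z[:, 1:] - 1].sum()
    return float(total)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def log_poisson_loglik(state: MCMCState, frame: StudyFrame) -> float:
    """Poisson log likelihood sum_ij [y log(E theta) - E theta - log y!]."""
    log_theta = state.log_theta(frame)
    if not np.all(np.isfinite(log_theta)):
        i, j = np.argwhere(~np.isfinite(log_theta))[0]
        raise ValidationError(
            f"non-finite linear predictor at area {frame.area_ids[i]!r}, "
            f"time {frame.time_ids[j]!r}"
        )
    mu = frame.E * np.exp(log_theta)
    return float(np.sum(frame.y * np.log(mu) - mu - gammaln(frame.y + 1.0)))


def _cell_loglik_terms(frame: StudyFrame, log_theta: np.ndarray) -> np.ndarray:
    mu = frame.E * np.exp(log_theta)
    return frame.y * np.log(mu) - mu - gammaln(frame.y + 1.0)


# ---------------------------------------------------------------------------
# block updates
# ---------------------------------------------------------------------------

def update_Z(
    state: MCMCState,
    frame: StudyFrame,
    rng: np.random.Generator,
    *,
    prior_only: bool = False,
) -> MCMCState:
    """Resample every label from its exact categorical full conditional.

    For cell (i, j) the full conditional over r in 1..G is proportional to
    Poisson(y_ij | E_ij theta_ij(r)) * f(r | Z_{i,j-1}) * f(Z_{i,j+1} | r),
    where the last factor (including its r-dependent normalizer) appears
    only for j < J.  The sweep visits time slices in order, vectorized over
    areas.
    """
    G = state.lam.shape[0]
    if G == 1:
        return state.copy()
    new = state.copy()
    N, J = frame.N, frame.J
    xb_u = (frame.X @ state.beta if state.beta.size else 0.0) + state.u
    M = _penalty_matrix(new.delta, G)
    logM = np.log(M)
    logp0 = np.log(penalty_probs(None, new.delta, G))
    lam = new.lam
    for j in range(J):
        # likelihood term per area x candidate label
        if prior_only:
            loglik = np.zeros((N, G))
        else:
            lt = xb_u[:, j][:, None] + lam[None, :]          # (N, G)
            log_mu = np.log(frame.E[:, j])[:, None] + lt
            with np.errstate(over="ignore"):
                mu = np.exp(log_mu)  # inf -> loglik -inf -> weight 0
            loglik = frame.y[:, j][:, None] * log_mu - mu
        if j == 0:
            logprior = np.broadcast_to(logp0, (N, G)).copy()
        else:
            logprior = logM[new.Z[:, j - 1] - 1, :]
        if j < J - 1:
            logprior = logprior + logM[:, new.Z[:, j + 1] - 1].T
        logw = loglik + logprior
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        uu = rng.random(N)
        new.Z[:, j] = 1 + (uu[:, None] > cum).sum(axis=1)
    return new


def update_lambda(
    state: MCMCState,
    frame: StudyFrame,
    rng: np.random.Generator,
    *,
    step: float = 0.05,
    prior_only: bool = False,
    stats: dict | None = None,
) -> MCMCState:
    """Random-walk Metropolis on each ordered intercept lambda_k.

    Proposals falling outside (lambda_{k-1}, lambda_{k+1}) are rejected, so
    the ordering constraint of the uniform order prior holds by
    construction; within the interval the prior is flat and the acceptance
    ratio is the Poisson likelihood ratio over cells currently assigned to
    label k.
    """
    new = state.copy()
    G = new.lam.shape[0]
    xb_u = (frame.X @ new.beta if new.beta.size else 0.0) + new.u
    acc = 0
    for k in range(G):
        lo = new.lam[k - 1] if k > 0 else -np.inf
        hi = new.lam[k + 1] if k < G - 1 else np.inf
        prop = new.lam[k] + step * rng.standard_normal()
        if not (lo < prop < hi):
            continue
        if prior_only:
            new.lam[k] = prop
            acc += 1
            continue
        mask = new.Z == (k + 1)
        if not mask.any():
            new.lam[k] = prop
            acc += 1
            continue
        y_k = frame.y[mask]
        base = frame.E[mask] * np.exp(xb_u[mask])
        with np.errstate(over="ignore"):
            dll = (
                y_k.sum() * (prop - new.lam[k])
                - base.sum() * (np.exp(prop) - np.exp(new.lam[k]))
            )
        if np.log(rng.random()) < dll:
            new.lam[k] = prop
            acc += 1
    if stats is not None:
        stats["accept"] = acc
        stats["propose"] = G
    return new


def update_delta(
    state: MCMCState,
    rng: np.random.Generator,
    *,
    bounds: tuple[float, float] = (1.0, 100.0),
    step: float = 20.0,
    G: int | None = None,
    prior_only: bool = False,
    stats: dict | None = None,
) -> MCMCState:
    """Random-walk Metropolis on the label penalty delta.

    The target is the product over cells of the penalty-process label
    probabilities, times the uniform prior on ``bounds``; proposals outside
    the support are rejected.  In prior-only mode the label term is
    switched off and the chain targets Uniform(L, U) itself.
    """
    new = state.copy()
    L, U = bounds
    G = G or new.lam.shape[0]
    prop = new.delta + step * rng.standard_normal()
    if stats is not None:
        stats["propose"] = 1
        stats["accept"] = 0
    if not (L <= prop <= U):
        return new
    if prior_only:
        dll = 0.0
    else:
        dll = _log_penalty_chain(new.Z, prop, G) - _log_penalty_chain(
            new.Z, new.delta, G
        )
    if np.log(rng.random()) < dll:
        new.delta = float(prop)
        if stats is not None:
            stats["accept"] = 1
    return new


def _quad_forms(u: np.ndarray, Q: np.ndarray, rhoT: float) -> float:
    """u_1' Q u_1 + sum_{j>=2} (u_j - rho u_{j-1})' Q (u_j - rho u_{j-1})."""
    total = float(u[:, 0] @ Q @ u[:, 0])
    for j in range(1, u.shape[1]):
        v = u[:, j] - rhoT * u[:, j - 1]
        total += float(v @ Q @ v)
    return total


def _graph_coloring(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Partition areas into independent sets (no two neighbours share a set)."""
    import networkx as nx

    g = nx.from_numpy_array(graph.W.astype(int))
    colors = nx.coloring.greedy_color(g, strategy="largest_first")
    ncol = max(colors.values()) + 1
    return [
        np.array([i for i, c in colors.items() if c == col], dtype=int)
        for col in range(ncol)
    ]


def update_u(
    state: MCMCState,
    frame: StudyFrame,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
    *,
    step: float = 0.1,
    prior_only: bool = False,
    cell_dloglik: Callable[[np.ndarray, int, np.ndarray, np.ndarray], np.ndarray] | None = None,
    coloring: list[np.ndarray] | None = None,
    stats: dict | None = None,
) -> MCMCState:
    """Metropolis sweep over the spatio-temporal random effects u_ij.

    Sites are updated in conditionally independent blocks (a graph colouring
    of the adjacency structure, one time slice at a time), which makes the
    single-site accept/reject decisions exact while staying vectorized.  The
    prior contribution combines the ICAR quadratic form of slices j-1, j and
    j+1 through the AR(1) structure.  After the full sweep u is re-centred
    to sum to zero across all cells; the removed mean is discarded (the
    cluster intercepts absorb the level).

    ``cell_dloglik(sites, j, u_old, u_new)`` may replace the Poisson
    likelihood difference; used by tests to check the Gaussian-field
    conditional against closed forms.
    """
    if state.tau2 <= 0:
        raise ValidationError("tau2 must be positive")
    new = state.copy()
    N, J = frame.N, frame.J
    Q = graph.Q
    qdiag = np.diag(Q)
    if coloring is None:
        coloring = _graph_coloring(graph)
    if cell_dloglik is None and not prior_only:
        xb = frame.X @ new.beta if new.beta.size else np.zeros((N, J))
        lamz = new.lam[new.Z - 1]

        def cell_dloglik(sites: np.ndarray, j: int, u_old: np.ndarray, u_new: np.ndarray) -> np.ndarray:
            off = xb[sites, j] + lamz[sites, j]
            mu_old = frame.E[sites, j] * np.exp(off + u_old)
            mu_new = frame.E[sites, j] * np.exp(off + u_new)
            return frame.y[sites, j] * (u_new - u_old) - (mu_new - mu_old)

    rho = new.rhoT
    n_acc = 0
    n_prop = 0
    for j in range(J):
        for sites in coloring:
            eps = step * rng.standard_normal(sites.size)
            u_old = new.u[sites, j]
            u_new = u_old + eps
            # prior quadratic-form change; v_j = u_j - rho u_{j-1} (v_1 = u_1)
            v_j = new.u[:, j] - (rho * new.u[:, j - 1] if j > 0 else 0.0)
            dquad = 2.0 * eps * (Q @ v_j)[sites] + eps**2 * qdiag[sites]
            if j < J - 1:
                v_next = new.u[:, j + 1] - rho * new.u[:, j]
                dquad += -2.0 * rho * eps * (Q @ v_next)[sites] + rho**2 * eps**2 * qdiag[sites]
            dlp = -dquad / (2.0 * new.tau2)
            if cell_dloglik is not None and not prior_only:
                dlp = dlp + cell_dloglik(sites, j, u_old, u_new)
            accept = np.log(rng.random(sites.size)) < dlp
            new.u[sites[accept], j] = u_new[accept]
            n_acc += int(accept.sum())
            n_prop += sites.size
    new.u -= new.u.mean()
    if stats is not None:
        stats["accept"] = n_acc
        stats["propose"] = n_prop
    return new


def update_tau2(
    state: MCMCState,
    graph: AdjacencyGraph,
    config: ModelConfig,
    rng: np.random.Generator,
) -> MCMCState:
    """Conjugate Gibbs draw of the random-effect variance tau2.

    Full conditional: Inverse-Gamma(a + rank(Q) J / 2, b + quad/2) with
    rank(Q) = N - 1 for a connected graph and quad the ICAR/AR(1) quadratic
    form of u.  In prior-only mode the u-term is switched off and the draw
    is from the IG(a, b) prior itself.
    """
    new = state.copy()
    a, b = config.tau2_prior
    if config.prior_only:
        shape, scale = a, b
    else:
        rank = graph.N - 1
        quad = _quad_forms(new.u, graph.Q, new.rhoT)
        shape = a + rank * new.u.shape[1] / 2.0
        scale = b + quad / 2.0
    # IG(shape, scale) via reciprocal of Gamma(shape, rate=scale)
    new.tau2 = float(scale / rng.gamma(shape))
    return new


def update_rhoT(
    state: MCMCState,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
    *,
    step: float = 0.2,
    prior_only: bool = False,
    stats: dict | None = None,
) -> MCMCState:
    """Random-walk Metropolis on the temporal autocorrelation rho_T in (0, 1).

    The target is the Gaussian AR(1) transition density of u_2..u_J under
    the ICAR precision (whose normalizer does not involve rho_T), times the
    flat prior; proposals outside (0, 1) are rejected.  With a single time
    point rho_T is not identified and the state is returned unchanged.
    """
    new = state.copy()
    if new.u.shape[1] < 2 and not prior_only:
        return new
    prop = new.rhoT + step * rng.standard_normal()
    if stats is not None:
        stats["propose"] = 1
        stats["accept"] = 0
    if not (0.0 < prop < 1.0):
        return new
    if prior_only:
        dll = 0.0
    else:
        Q = graph.Q
        quad_new = quad_old = 0.0
        for j in range(1, new.u.shape[1]):
            v_new = new.u[:, j] - prop * new.u[:, j - 1]
            v_old = new.u[:, j] - new.rhoT * new.u[:, j - 1]
            quad_new += float(v_new @ Q @ v_new)
            quad_old += float(v_old @ Q @ v_old)
        dll = -(quad_new - quad_old) / (2.0 * new.tau2)
    if np.log(rng.random()) < dll:
        new.rhoT = float(prop)
        if stats is not None:
            stats["accept"] = 1
    return new


def update_beta(
    state: MCMCState,
    frame: StudyFrame,
    config: ModelConfig,
    rng: np.random.Generator,
    *,
    step: float = 0.01,
    prior_only: bool = False,
    stats: dict | None = None,
) -> MCMCState:
    """Joint random-walk Metropolis on the regression coefficients.

    Spherical Gaussian proposal; target is the Poisson likelihood times the
    N(0, v I) prior.  A no-op when the model has no covariates.
    """
    new = state.copy()
    p = new.beta.size
    if p == 0:
        if stats is not None:
            stats["propose"] = 0
            stats["accept"] = 0
        return new
    prop = new.beta + step * rng.standard_normal(p)
    dlp = -0.5 * (prop @ prop - new.beta @ new.beta) / config.beta_prior_var
    if not prior_only:
        off = new.u + new.lam[new.Z - 1]
        lt_old = frame.X @ new.beta + off
        lt_new = frame.X @ prop + off
        mu_old = frame.E * np.exp(lt_old)
        mu_new = frame.E * np.exp(lt_new)
        dlp += float(np.sum(frame.y * (lt_new - lt_old) - (mu_new - mu_old)))
    if stats is not None:
        stats["propose"] = 1
        stats["accept"] = 0
    if np.log(rng.random()) < dlp:
        new.beta = prop
        if stats is not None:
            stats["accept"] = 1
    return new


def _update_beta_u_shear(
    state: MCMCState,
    frame: StudyFrame,
    graph: AdjacencyGraph,
    config: ModelConfig,
    rng: np.random.Generator,
    *,
    step: float = 0.01,
    stats: dict | None = None,
) -> MCMCState:
    """Likelihood-preserving joint move on (beta, u).

    Proposes beta' = beta + e and u' = u - X e, which leaves every linear
    predictor (hence the Poisson likelihood) unchanged; the acceptance
    ratio involves only the Gaussian field prior of u and the beta prior.
    The map is a unit-Jacobian shear with a symmetric proposal, so plain
    Metropolis acceptance is valid.  Requires centered covariates (which
    :func:`run_mcmc` uses internally) so that u' keeps its zero overall sum.

    This move travels along the ridge where covariate effects trade off
    against the random field -- the direction in which the plain
    random-walk beta update mixes slowly.
    """
    new = state.copy()
    p = new.beta.size
    if p == 0:
        return new
    eps = step * rng.standard_normal(p)
    beta_prop = new.beta + eps
    u_prop = new.u - frame.X @ eps
    Q = graph.Q
    dquad = _quad_forms(u_prop, Q, new.rhoT) - _quad_forms(new.u, Q, new.rhoT)
    dlp = -dquad / (2.0 * new.tau2)
    dlp += -0.5 * (beta_prop @ beta_prop - new.beta @ new.beta) / config.beta_prior_var
    if stats is not None:
        stats["propose"] = 1
        stats["accept"] = 0
    if np.log(rng.random()) < dlp:
        new.beta = beta_prop
        new.u = u_prop - u_prop.mean()
        if stats is not None:
            stats["accept"] = 1
    return new


def _update_lambda_u_shear(
    state: MCMCState,
    frame: StudyFrame,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
    *,
    step: float = 0.05,
    stats: dict | None = None,
) -> MCMCState:
    """Likelihood-preserving joint move on (lambda_k, u).

    Proposes lambda_k' = lambda_k + d together with u' = u - d on the cells
    currently labelled k, so every linear predictor is unchanged; the
    acceptance ratio involves only the Gaussian field prior (the order
    prior is flat inside the admissible interval, outside which the move is
    rejected).  Afterwards the overall mean of u is moved into a common
    shift of all lambdas, which also leaves the likelihood untouched.
    Travels the ridge where a cluster's intercept trades off against the
    smooth field.
    """
    new = state.copy()
    G = new.lam.shape[0]
    Q = graph.Q
    acc = 0
    for k in range(G):
        mask = new.Z == (k + 1)
        d = step * rng.standard_normal()
        lo = new.lam[k - 1] if k > 0 else -np.inf
        hi = new.lam[k + 1] if k < G - 1 else np.inf
        prop = new.lam[k] + d
        if not (lo < prop < hi):
            continue
        u_prop = new.u - d * mask
        dquad = _quad_forms(u_prop, Q, new.rhoT) - _quad_forms(new.u, Q, new.rhoT)
        if np.log(rng.random()) < -dquad / (2.0 * new.tau2):
            new.lam[k] = prop
            new.u = u_prop
            acc += 1
    m = new.u.mean()
    new.u -= m
    new.lam += m
    if stats is not None:
        stats["accept"] = acc
        stats["propose"] = G
    return new


def _update_z_u_swap(
    state: MCMCState,
    frame: StudyFrame,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
    *,
    coloring: list[np.ndarray] | None = None,
    stats: dict | None = None,
) -> MCMCState:
    """Likelihood-preserving joint move on (Z_ij, u_ij).

    Each cell proposes stepping its label one group up or down while
    shifting u_ij by the opposite intercept difference, leaving the linear
    predictor (hence the likelihood) unchanged.  Acceptance weighs the
    Gaussian field prior against the label penalty process.  Updated in the
    same conditionally independent colour/slice blocks as :func:`update_u`.
    This unsticks label configurations that the exact conditional
    :func:`update_Z` leaves metastable once u has absorbed a cluster jump.
    """
    new = state.copy()
    G = new.lam.shape[0]
    if G == 1:
        return new
    N, J = new.u.shape
    Q = graph.Q
    qdiag = np.diag(Q)
    if coloring is None:
        coloring = _graph_coloring(graph)
    logp0 = np.log(penalty_probs(None, new.delta, G))
    logM = np.log(_penalty_matrix(new.delta, G))
    rho = new.rhoT
    n_acc = 0
    n_prop = 0
    for j in range(J):
        for sites in coloring:
            z_old = new.Z[sites, j]
            direction = np.where(rng.random(sites.size) < 0.5, -1, 1)
            z_new = z_old + direction
            ok = (z_new >= 1) & (z_new <= G)
            if not ok.any():
                continue
            s_ok = sites[ok]
            zo, zn = z_old[ok], z_new[ok]
            eps = new.lam[zo - 1] - new.lam[zn - 1]
            v_j = new.u[:, j] - (rho * new.u[:, j - 1] if j > 0 else 0.0)
            dquad = 2.0 * eps * (Q @ v_j)[s_ok] + eps**2 * qdiag[s_ok]
            if j < J - 1:
                v_next = new.u[:, j + 1] - rho * new.u[:, j]
                dquad += -2.0 * rho * eps * (Q @ v_next)[s_ok] + rho**2 * eps**2 * qdiag[s_ok]
            dlp = -dquad / (2.0 * new.tau2)
            if j == 0:
                dlp += logp0[zn - 1] - logp0[zo - 1]
            else:
                zprev = new.Z[s_ok, j - 1]
                dlp += logM[zprev - 1, zn - 1] - logM[zprev - 1, zo - 1]
            if j < J - 1:
                znext = new.Z[s_ok, j + 1]
                dlp += logM[zn - 1, znext - 1] - logM[zo - 1, znext - 1]
            accept = np.log(rng.random(s_ok.size)) < dlp
            new.Z[s_ok[accept], j] = zn[accept]
            new.u[s_ok[accept], j] += eps[accept]
            n_acc += int(accept.sum())
            n_prop += s_ok.size
    if stats is not None:
        stats["accept"] = n_acc
        stats["propose"] = n_prop
    return new


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _initial_state(frame: StudyFrame, config: ModelConfig) -> MCMCState:
    a, b = config.tau2_prior
    G = config.G
    raw = np.log((frame.y + 0.5) / frame.E)
    # regression effects start at a least-squares fit of the empirical
    # log-risk (the usual GLM-style start for CAR samplers); burn-in from
    # beta = 0 would otherwise need tens of thousands of random-walk steps
    beta0 = np.zeros(frame.p)
    if frame.p and not config.prior_only:
        Xf = frame.X.reshape(-1, frame.p)
        beta0, *_ = np.linalg.lstsq(Xf, raw.reshape(-1) - raw.mean(), rcond=None)
        raw = raw - (frame.X @ beta0)
    if G == 1:
        lam = np.array([float(np.median(raw))])
    else:
        qs = np.linspace(0, 1, G + 2)[1:-1]
        lam = np.quantile(raw, qs)
        # enforce strict ordering when quantiles tie
        for k in range(1, G):
            if lam[k] <= lam[k - 1]:
                lam[k] = lam[k - 1] + 1e-6
    # assign each cell to the nearest initial intercept (kmeans-style start);
    # starting every label at G* leaves chains metastable, with u absorbing
    # the cluster jumps and tau2 inflated
    Z = 1 + np.argmin(np.abs(raw[:, :, None] - lam[None, None, :]), axis=2)
    return MCMCState(
        beta=beta0,
        lam=np.asarray(lam, dtype=float),
        Z=Z,
        delta=float(config.delta_bounds[0]),
        u=np.zeros((frame.N, frame.J)),
        tau2=b / (a + 1.0),  # prior mode
        rhoT=0.5,
    )


class _StepAdapter:
    """Robbins-Monro log-scale step adaptation towards a target rate (burn-in only)."""

    def __init__(self, step: float, target: float):
        self.step = step
        self.target = target
        self.acc = 0
        self.prop = 0

    def record(self, stats: dict) -> None:
        self.acc += stats.get("accept", 0)
        self.prop += stats.get("propose", 0)

    def adapt(self) -> None:
        if self.prop == 0:
            return
        rate = self.acc / self.prop
        self.step *= float(np.exp(0.6 * (rate - self.target)))
        self.step = float(np.clip(self.step, 1e-6, 1e6))
        self.acc = 0
        self.prop = 0


def run_mcmc(
    frame: StudyFrame,
    graph: AdjacencyGraph,
    config: ModelConfig,
) -> PosteriorSamples:
    """Fit the localized CAR model by Metropolis-within-Gibbs.

    The block sweep (u, tau2, rho_T, beta, lambda, Z, delta) is executed
    ``n_iter`` times; thinned post-burn-in states are stored together with
    the fitted relative-risk surface theta and per-block acceptance rates.
    A single seeded generator drives all randomness, so identical seeds give
    identical chains.
    """
    if frame.E is None:
        raise ValidationError("expected counts missing; run compute_expected_counts first")
    if list(graph.area_ids) != list(frame.area_ids):
        raise ValidationError("adjacency and study frame use different area orderings")
    # Sample in a centered-covariate parameterization: the level x̄'beta is
    # absorbed by the cluster intercepts during sampling (removing the
    # beta/lambda posterior ridge) and shifted back before storage, so the
    # stored lambdas refer to raw-scale covariates and
    # theta = exp(x'beta + u + lambda_Z) holds for every stored sample.
    from dataclasses import replace as _replace

    xbar = frame.X.reshape(-1, frame.p).mean(axis=0) if frame.p else np.zeros(0)
    cframe = _replace(frame, X=frame.X - xbar, E=frame.E)
    rng = np.random.default_rng(config.seed)
    state = _initial_state(cframe, config)
    state.validate(config)
    if not config.prior_only and not np.isfinite(log_poisson_loglik(state, cframe)):
        raise ValidationError(
            f"non-finite posterior density at initialization: state={state!r}"
        )
    coloring = _graph_coloring(graph)
    po = config.prior_only

    adapters = {
        "u": _StepAdapter(config.step_u, config.target_accept_vector),
        "lambda": _StepAdapter(config.step_lambda, config.target_accept_scalar),
        "delta": _StepAdapter(config.step_delta, config.target_accept_scalar),
        "rhoT": _StepAdapter(config.step_rhoT, config.target_accept_scalar),
        "beta": _StepAdapter(config.step_beta, config.target_accept_vector),
        "beta_u": _StepAdapter(config.step_beta, config.target_accept_vector),
        "lambda_u": _StepAdapter(config.step_lambda, config.target_accept_scalar),
        "z_u": _StepAdapter(1.0, 0.0),  # no tunable step; tracked for the rate log
    }
    totals = {k: [0, 0] for k in adapters}

    S = (config.n_iter - config.burnin) // config.thin
    p, G, N, J = frame.p, config.G, frame.N, frame.J
    store = PosteriorSamples(
        beta=np.empty((S, p)),
        lam=np.empty((S, G)),
        Z=np.empty((S, N, J), dtype=np.int8),
        delta=np.empty(S),
        u=np.empty((S, N, J)),
        tau2=np.empty(S),
        rhoT=np.empty(S),
        theta=np.empty((S, N, J)),
        acceptance={},
        config=config,
        area_ids=list(frame.area_ids),
        time_ids=list(frame.time_ids),
        covariates=list(frame.covariates),
    )

    s = 0
    for it in range(config.n_iter):
        st: dict[str, dict] = {k: {} for k in adapters}
        if not po:
            state = update_u(
                state, cframe, graph, rng,
                step=adapters["u"].step, coloring=coloring, stats=st["u"],
            )
        state = update_tau2(state, graph, config, rng)
        state = update_rhoT(
            state, graph, rng, step=adapters["rhoT"].step,
            prior_only=po, stats=st["rhoT"],
        )
        state = update_beta(
            state, cframe, config, rng, step=adapters["beta"].step,
            prior_only=po, stats=st["beta"],
        )
        if not po and frame.p:
            state = _update_beta_u_shear(
                state, cframe, graph, config, rng,
                step=adapters["beta_u"].step, stats=st["beta_u"],
            )
        state = update_lambda(
            state, cframe, rng, step=adapters["lambda"].step,
            prior_only=po, stats=st["lambda"],
        )
        state = update_Z(state, cframe, rng, prior_only=po)
        if not po:
            state = _update_lambda_u_shear(
                state, cframe, graph, rng,
                step=adapters["lambda_u"].step, stats=st["lambda_u"],
            )
            state = _update_z_u_swap(
                state, cframe, graph, rng, coloring=coloring, stats=st["z_u"],
            )
        state = update_delta(
            state, rng, bounds=config.delta_bounds,
            step=adapters["delta"].step, G=G, prior_only=po, stats=st["delta"],
        )

        for k, ad in adapters.items():
            ad.record(st[k])
            totals[k][0] += st[k].get("accept", 0)
            totals[k][1] += st[k].get("propose", 0)
        if it < config.burnin and (it + 1) % config.adapt_interval == 0:
            for ad in adapters.values():
                ad.adapt()

        if it >= config.burnin and (it - config.burnin) % config.thin == 0 and s < S:
            store.beta[s] = state.beta
            # shift the sampling-parameterization intercepts back to the
            # raw-covariate scale (see the centering note above)
            store.lam[s] = state.lam - (xbar @ state.beta if state.beta.size else 0.0)
            store.Z[s] = state.Z
            store.delta[s] = state.delta
            store.u[s] = state.u
            store.tau2[s] = state.tau2
            store.rhoT[s] = state.rhoT
            store.theta[s] = np.exp(state.log_theta(cframe)) if not po else np.nan
            s += 1

    store.acceptance = {
        k: (totals[k][0] / totals[k][1] if totals[k][1] else float("nan"))
        for k in totals
    }
    return store
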