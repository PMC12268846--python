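"""Unit tests for the localized CAR sampler: likelihood, penalty process,
and every Metropolis-within-Gibbs block against independent oracles."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import poisson

import stcarlocal as sc
from stcarlocal.dataio import ValidationError
from stcarlocal.model import (
    MCMCState,
    _penalty_matrix,
    middle_label,
    update_Z,
    update_beta,
    update_delta,
    update_lambda,
    update_rhoT,
    update_tau2,
    update_u,
)


def make_state(frame, G=1, lam=None, **kw):
    defaults = dict(
        beta=np.zeros(frame.p),
        lam=np.asarray(lam if lam is not None else np.linspace(-0.5, 0.5, G) if G > 1 else [0.0], dtype=float),
        Z=np.ones((frame.N, frame.J), dtype=int),
        delta=1.0,
        u=np.zeros((frame.N, frame.J)),
        tau2=0.1,
        rhoT=0.5,
    )
    defaults.update(kw)
    return MCMCState(**defaults)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def one_cell_frame(y, E):
    frame = sc.StudyFrame(["a"], ["t"], np.array([[y]]), np.array([[1000]]), np.zeros((1, 1, 0)))
    frame.E = np.array([[float(E)]])
    return frame


@pytest.mark.parametrize(
    "y, expected",
    [(0, -1.0), (2, -1.0 - np.log(2.0))],
)
def test_loglik_closed_forms_unit_rate(y, expected):
    frame = one_cell_frame(y, 1.0)
    state = make_state(frame)
    assert sc.log_poisson_loglik(state, frame) == pytest.approx(expected, abs=1e-12)


def test_loglik_matches_cellwise_reference(sim):
    frame, _ = sim
    rng = np.random.default_rng(1)
    state = make_state(
        frame, G=2, lam=[-0.3, 0.4],
        beta=rng.normal(0, 0.01, frame.p),
        Z=rng.integers(1, 3, (frame.N, frame.J)),
        u=rng.normal(0, 0.2, (frame.N, frame.J)),
    )
    # naive reference: loop over cells
    ref = 0.0
    for i in range(frame.N):
        for j in range(frame.J):
            lt = frame.X[i, j] @ state.beta + state.u[i, j] + state.lam[state.Z[i, j] - 1]
            mu = frame.E[i, j] * np.exp(lt)
            ref += frame.y[i, j] * np.log(mu) - mu - gammaln(frame.y[i, j] + 1)
    assert sc.log_poisson_loglik(state, frame) == pytest.approx(ref, rel=1e-12)


def test_loglik_flags_nonfinite_predictor(tiny_frame):
    state = make_state(tiny_frame)
    state.u[1, 0] = np.inf
    with pytest.raises(ValidationError, match="'b'"):
        sc.log_poisson_loglik(state, tiny_frame)


# ---------------------------------------------------------------------------
# penalty process
# ---------------------------------------------------------------------------

def test_penalty_single_group_is_degenerate():
    np.testing.assert_array_equal(sc.penalty_probs(None, 7.3, 1), [1.0])


def test_penalty_first_slice_symmetric_about_middle():
    p = sc.penalty_probs(None, 0.7, 3)
    assert p[0] == pytest.approx(p[2])
    assert p[1] == p.max()


def test_penalty_matches_direct_formula():
    r = np.arange(1, 4)
    gstar = 2  # G = 3
    raw = np.exp(-1.0 * ((r - 1) ** 2 + (r - gstar) ** 2))
    np.testing.assert_allclose(sc.penalty_probs(1, 1.0, 3), raw / raw.sum(), rtol=1e-12)


@pytest.mark.parametrize("G", range(1, 8))
@pytest.mark.parametrize("delta", [1.0, 10.0, 100.0])
def test_penalty_probs_normalized(G, delta):
    for z_prev in [None, 1, G]:
        p = sc.penalty_probs(z_prev, delta, G)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)


def test_middle_label_rule():
    assert [middle_label(G) for G in (1, 2, 3, 4, 5)] == [1, 1, 2, 2, 3]


def test_middle_label_probability_monotone_in_delta():
    for G in (3, 5):
        probs = [sc.penalty_probs(None, d, G)[middle_label(G) - 1] for d in (1, 10, 100)]
        assert probs[0] < probs[1] <= probs[2]
        assert probs[2] > 1 - 1e-8


# ---------------------------------------------------------------------------
# Z update
# ---------------------------------------------------------------------------

def test_update_Z_single_group_is_identity(tiny_frame):
    state = make_state(tiny_frame)
    rng = np.random.default_rng(0)
    for _ in range(20):
        new = update_Z(state, tiny_frame, rng)
        np.testing.assert_array_equal(new.Z, state.Z)


def test_update_Z_likelihood_domination(pair_graph):
    """A huge count matched by the top intercept pins the label there."""
    frame = sc.StudyFrame(
        ["a", "b"], ["t"], y=np.array([[60_000], [5_000]]),
        n=np.array([[100_000], [100_000]]), X=np.zeros((2, 1, 0)),
    )
    frame = sc.compute_expected_counts(frame)
    lam = np.array([np.log(5_000 / frame.E[1, 0]), np.log(60_000 / frame.E[0, 0])])
    state = make_state(frame, G=2, lam=lam, Z=np.array([[1], [2]]))
    rng = np.random.default_rng(3)
    hits = sum(update_Z(state, frame, rng).Z[0, 0] == 2 for _ in range(200))
    assert hits == 200


# ---------------------------------------------------------------------------
# lambda update
# ---------------------------------------------------------------------------

def test_lambda_empty_group_random_walks_freely(tiny_frame):
    """A group with no assigned cells accepts every in-interval proposal."""
    state = make_state(tiny_frame, G=2, lam=[0.0, 50.0], Z=np.full((2, 2), 2))
    rng = np.random.default_rng(2)
    changed = 0
    for _ in range(500):
        new = update_lambda(state, tiny_frame, rng, step=0.5)
        changed += new.lam[0] != state.lam[0]
        state = new
    assert changed == 500  # proposals never reach lambda_2 = 50
    assert state.lam[0] < state.lam[1]


def test_lambda_posterior_matches_griddy_quadrature():
    """Single cell, single group: MH chain vs numerical posterior CDF."""
    frame = one_cell_frame(20, 10.0)
    state = make_state(frame)
    rng = np.random.default_rng(6)
    draws = np.empty(10_000)
    for s in range(draws.size):
        state = update_lambda(state, frame, rng, step=0.35)
        draws[s] = state.lam[0]
    grid = np.linspace(-1.5, 2.5, 4001)
    logpost = 20 * grid - 10 * np.exp(grid)
    dens = np.exp(logpost - logpost.max())
    cdf = np.cumsum(dens) / dens.sum()
    emp = np.searchsorted(np.sort(draws), grid) / draws.size
    assert np.max(np.abs(emp - cdf)) < 0.05


def test_lambda_ordering_preserved_under_joint_updates(sim):
    frame, _ = sim
    state = make_state(frame, G=3, lam=[-0.5, 0.0, 0.5])
    rng = np.random.default_rng(9)
    for _ in range(2000):
        state = update_lambda(state, frame, rng, step=0.2)
        state = update_Z(state, frame, rng)
        assert np.all(np.diff(state.lam) > 0)


# ---------------------------------------------------------------------------
# delta update
# ---------------------------------------------------------------------------

def test_delta_drifts_to_upper_bound_when_all_labels_middle():
    """With every label at G* the penalty target increases in delta, so the
    chain mean settles above the support midpoint, matching quadrature."""
    N = 500
    frame = sc.StudyFrame(
        [f"a{i}" for i in range(N)], ["t"], np.full((N, 1), 2),
        np.full((N, 1), 50), np.zeros((N, 1, 0)),
    )
    state = make_state(frame, G=3, lam=[-1.0, 0.0, 1.0], Z=np.full((N, 1), 2))
    rng = np.random.default_rng(12)
    trace = []
    for _ in range(12_000):
        state = update_delta(state, rng, step=25.0, G=3)
        trace.append(state.delta)
    chain_mean = np.mean(trace[4000:])
    grid = np.linspace(1, 100, 20_000)
    logpost = -N * np.log1p(2 * np.exp(-grid))  # log f(G* | delta)^N
    w = np.exp(logpost - logpost.max())
    exact_mean = float((grid * w).sum() / w.sum())
    assert chain_mean > 50.5
    assert abs(chain_mean - exact_mean) < 2.0


def test_delta_stays_inside_support():
    frame = sc.StudyFrame(["a", "b"], ["t"], np.array([[1], [2]]), np.array([[10], [10]]), np.zeros((2, 1, 0)))
    state = make_state(frame, G=2, lam=[-0.5, 0.5], Z=np.array([[1], [2]]), delta=99.0)
    rng = np.random.default_rng(1)
    for _ in range(500):
        state = update_delta(state, rng, step=300.0, G=2)
        assert 1.0 <= state.delta <= 100.0


# ---------------------------------------------------------------------------
# u update
# ---------------------------------------------------------------------------

def test_u_recentered_after_each_sweep(sim):
    frame, _ = sim
    graph = sc.make_lattice_graph(4, 4)
    state = make_state(frame, u=np.random.default_rng(0).normal(0, 0.3, (frame.N, frame.J)) )
    state.u -= state.u.mean()
    rng = np.random.default_rng(5)
    for _ in range(20):
        state = update_u(state, frame, graph, rng, step=0.2)
        assert abs(state.u.sum()) < 1e-10


def test_u_requires_positive_tau2(tiny_frame, pair_graph):
    state = make_state(tiny_frame, tau2=0.0)
    with pytest.raises(ValidationError):
        update_u(state, tiny_frame, pair_graph, np.random.default_rng(0))


def test_u_gaussian_field_matches_closed_form_conditional():
    """Path graph, one time slice, Gaussian observation hook: the chain
    mean reproduces the sum-constrained GMRF posterior mean."""
    graph = sc.AdjacencyGraph(["a", "b", "c"], np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))
    frame = sc.StudyFrame(["a", "b", "c"], ["t0"], np.ones((3, 1), int), np.full((3, 1), 10), np.zeros((3, 1, 0)))
    frame = sc.compute_expected_counts(frame)
    obs = np.array([0.5, -0.2, 0.1])
    sig2, tau2 = 0.09, 0.5

    def gauss_dll(sites, j, u_old, u_new):
        return -((obs[sites] - u_new) ** 2 - (obs[sites] - u_old) ** 2) / (2 * sig2)

    A = graph.Q / tau2 + np.eye(3) / sig2
    kkt = np.block([[A, np.ones((3, 1))], [np.ones((1, 3)), np.zeros((1, 1))]])
    m_constrained = np.linalg.solve(kkt, np.concatenate([obs / sig2, [0.0]]))[:3]

    state = make_state(frame, tau2=tau2)
    rng = np.random.default_rng(4)
    total = np.zeros(3)
    kept = 0
    for it in range(30_000):
        state = update_u(state, frame, graph, rng, step=0.35, cell_dloglik=gauss_dll)
        if it >= 2_000:
            total += state.u[:, 0]
            kept += 1
    np.testing.assert_allclose(total / kept, m_constrained, atol=0.03)


# ---------------------------------------------------------------------------
# tau2 update
# ---------------------------------------------------------------------------

def test_tau2_zero_field_draws_from_incremented_prior(tiny_frame, pair_graph):
    """u = 0: the Gibbs draw is IG(a + rank*J/2, b) exactly."""
    a, b = 1.0, 0.01
    cfg = sc.ModelConfig(G=1, tau2_prior=(a, b), n_iter=2, burnin=1)
    state = make_state(tiny_frame)
    rng = np.random.default_rng(8)
    draws = np.array([update_tau2(state, pair_graph, cfg, rng).tau2 for _ in range(50_000)])
    shape = a + (pair_graph.N - 1) * tiny_frame.J / 2.0  # rank = N - 1
    assert draws.mean() == pytest.approx(b / (shape - 1), rel=0.03)
    assert (1.0 / draws).mean() == pytest.approx(shape / b, rel=0.03)


def test_tau2_analytic_posterior_moment_and_quadratic_scaling():
    graph = sc.make_lattice_graph(2, 2)
    frame = sc.StudyFrame(graph.area_ids, ["t0", "t1"], np.ones((4, 2), int), np.full((4, 2), 10), np.zeros((4, 2, 0)))
    frame = sc.compute_expected_counts(frame)
    rng0 = np.random.default_rng(3)
    u = rng0.normal(0, 0.3, (4, 2))
    u -= u.mean()
    a, b = 1.0, 0.01
    cfg = sc.ModelConfig(G=1, tau2_prior=(a, b), n_iter=2, burnin=1)
    rho = 0.4
    # independent quadratic form: explicit loops over the definition
    Q = graph.Q

    def quad(v):
        tot = v[:, 0] @ Q @ v[:, 0]
        for j in range(1, v.shape[1]):
            d = v[:, j] - rho * v[:, j - 1]
            tot += d @ Q @ d
        return tot

    for c in (1.0, 3.0):
        state = make_state(frame, u=c * u, rhoT=rho)
        rng = np.random.default_rng(10)
        draws = np.array([update_tau2(state, graph, cfg, rng).tau2 for _ in range(100_000)])
        shape = a + 3 * 2 / 2.0  # rank 3, J = 2
        scale = b + quad(c * u) / 2.0
        assert draws.mean() == pytest.approx(scale / (shape - 1), rel=0.01)


# ---------------------------------------------------------------------------
# rhoT update
# ---------------------------------------------------------------------------

def test_rhoT_stays_inside_unit_interval(sim):
    frame, _ = sim
    graph = sc.make_lattice_graph(4, 4)
    state = make_state(frame, u=np.random.default_rng(2).normal(0, 0.3, (frame.N, frame.J)))
    rng = np.random.default_rng(2)
    for _ in range(500):
        state = update_rhoT(state, graph, rng, step=2.0)
        assert 0.0 < state.rhoT < 1.0


def test_rhoT_not_updated_for_single_time_point(pair_graph):
    frame = sc.StudyFrame(["a", "b"], ["t"], np.ones((2, 1), int), np.full((2, 1), 10), np.zeros((2, 1, 0)))
    state = make_state(frame)
    rng = np.random.default_rng(0)
    for _ in range(50):
        assert update_rhoT(state, pair_graph, rng).rhoT == state.rhoT


def test_rhoT_recovers_generating_autocorrelation():
    """u simulated at rho_T = 0.8 with known tau2; posterior centred nearby."""
    graph = sc.make_lattice_graph(6, 6)
    _, truth = sc.simulate_dataset(
        graph, J=8, beta_true=(), lambda_true=(0.0,),
        tau2_true=0.1, rhoT_true=0.8, seed=14,
    )
    frame = sc.StudyFrame(graph.area_ids, [f"t{j}" for j in range(8)], np.ones((36, 8), int), np.full((36, 8), 10), np.zeros((36, 8, 0)))
    state = make_state(frame, u=truth.u_true, tau2=0.1)
    rng = np.random.default_rng(15)
    trace = []
    for _ in range(4000):
        state = update_rhoT(state, graph, rng, step=0.1)
        trace.append(state.rhoT)
    assert abs(np.mean(trace[1000:]) - 0.8) < 0.1


# ---------------------------------------------------------------------------
# beta update
# ---------------------------------------------------------------------------

def test_beta_noop_without_covariates(tiny_frame):
    state = make_state(tiny_frame)
    cfg = sc.ModelConfig(G=1, n_iter=2, burnin=1)
    new = update_beta(state, tiny_frame, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(new.beta, state.beta)


def test_beta_large_count_recovery():
    """Huge populations, field and intercept at truth: the conditional
    posterior of the single coefficient concentrates at its true value."""
    graph = sc.make_lattice_graph(4, 4)
    frame, truth = sc.simulate_dataset(
        graph, J=3, beta_true=(0.02,), lambda_true=(0.0,), tau2_true=0.0,
        covariate_ranges=((5.0, 35.0),), n_mean=1e6, n_sigma=0.0,
        baseline_rate=0.1, seed=30,
    )
    frame.E = 0.1 * frame.n  # the generating offsets, matching lambda = 0
    state = make_state(frame, beta=np.array([0.02]))
    cfg = sc.ModelConfig(G=1, n_iter=2, burnin=1)
    info = float(np.sum(frame.E * np.exp(frame.X[:, :, 0] * 0.02) * frame.X[:, :, 0] ** 2))
    sd = 1.0 / np.sqrt(info)
    state.beta = np.array([0.02 + 25 * sd])  # start well off the mode
    rng = np.random.default_rng(31)
    draws = np.empty(20_000)
    for s in range(draws.size):
        state = update_beta(state, frame, cfg, rng, step=2.5 * sd)
        draws[s] = state.beta[0]
    assert abs(draws[2000:].mean() - 0.02) < 0.002


def test_beta_prior_only_variance():
    graph = sc.make_lattice_graph(3, 3)
    frame, _ = sc.simulate_dataset(
        graph, J=2, beta_true=(0.02,), covariate_ranges=((5, 35),), n_mean=1000, seed=3
    )
    cfg = sc.ModelConfig(
        G=2, n_iter=22_000, burnin=2_000, thin=1, seed=11,
        prior_only=True, beta_prior_var=1.0, step_beta=1.0,
    )
    samples = sc.run_mcmc(frame, graph, cfg)
    assert samples.beta[:, 0].var() == pytest.approx(1.0, rel=0.05)


# ---------------------------------------------------------------------------
# full driver
# ---------------------------------------------------------------------------

def test_run_mcmc_seed_determinism(sim):
    frame, _ = sim
    graph = sc.make_lattice_graph(4, 4)
    cfg = sc.ModelConfig(G=2, n_iter=800, burnin=200, thin=2, seed=99)
    s1 = sc.run_mcmc(frame, graph, cfg)
    s2 = sc.run_mcmc(frame, graph, cfg)
    np.testing.assert_array_equal(s1.theta, s2.theta)
    np.testing.assert_array_equal(s1.Z, s2.Z)
    np.testing.assert_array_equal(s1.beta, s2.beta)


def test_run_mcmc_stored_samples_satisfy_model_identities(sim):
    """Ordering of lambda, label range, and the log-link identity
    theta = exp(x'beta + u + lambda_Z) hold at every stored sample."""
    frame, _ = sim
    graph = sc.make_lattice_graph(4, 4)
    cfg = sc.ModelConfig(G=3, n_iter=1200, burnin=200, thin=2, seed=4)
    s = sc.run_mcmc(frame, graph, cfg)
    assert np.all(np.diff(s.lam, axis=1) > 0)
    assert s.Z.min() >= 1 and s.Z.max() <= 3
    for k in range(0, s.S, 25):
        lt = frame.X @ s.beta[k] + s.u[k] + s.lam[k][s.Z[k] - 1]
        np.testing.assert_allclose(s.theta[k], np.exp(lt), rtol=1e-10)


def test_run_mcmc_null_data_calibrated_risk():
    """Flat truth (single group, no covariates, no field): every cell's
    posterior mean relative risk stays near 1."""
    graph = sc.make_lattice_graph(5, 5)
    frame, _ = sc.simulate_dataset(
        graph, J=2, beta_true=(), lambda_true=(0.0,), tau2_true=0.0,
        n_mean=20_000, seed=44,
    )
    cfg = sc.ModelConfig(G=1, n_iter=3000, burnin=1000, thin=2, seed=45)
    s = sc.run_mcmc(frame, graph, cfg)
    rr = s.theta.mean(axis=0)
    assert rr.min() > 0.8 and rr.max() < 1.25


def test_run_mcmc_rejects_mismatched_graph(sim):
    frame, _ = sim
    wrong = sc.AdjacencyGraph(["x", "y"], np.array([[0, 1], [1, 0]]))
    with pytest.raises(ValidationError, match="ordering"):
        sc.run_mcmc(frame, wrong, sc.ModelConfig(G=1, n_iter=10, burnin=1))


def test_config_validation():
    with pytest.raises(ValidationError):
        sc.ModelConfig(G=0)
    with pytest.raises(ValidationError):
        sc.ModelConfig(delta_bounds=(5.0, 5.0))
    with pytest.raises(ValidationError):
        sc.ModelConfig(n_iter=100, burnin=200)
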