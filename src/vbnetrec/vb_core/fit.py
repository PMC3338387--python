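"""Coordinate-ascent variational Bayes for spike-and-slab regression.

One sweep updates every penalized feature factor in a fresh random order,
then the hyper-posteriors (truncated-Beta inclusion fraction, Gamma noise and
slab precisions), then the non-random intercept/covariate effects, and
finally evaluates the evidence lower bound. Every step exactly maximizes the
lower bound over its own block, so the bound is non-decreasing per sweep up
to floating-point error — this is the primary correctness oracle.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence
from scipy.linalg.blas import daxpy
from scipy.special import gammaln, xlogy

from .problem import RegressionProblem, SpikeSlabPrior
from .state import FixedHyperparameters, VariationalState
from .truncbeta import truncated_beta_moments

__all__ = [
    "init_state",
    "update_feature",
    "update_hyperparameters",
    "update_unpenalized",
    "lower_bound",
    "fit_vb",
    "fit_restarts",
    "FitResult",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# initialization

def init_state(
    problem: RegressionProblem,
    prior: SpikeSlabPrior | None = None,
    seed: int | None = 0,
    fixed: FixedHyperparameters | None = None,
) -> VariationalState:
    """Randomized starting point: p_j ~ Uniform(0.05, 0.95), mu_j = 0,
    hyper-posteriors at their prior values. Deterministic given the seed."""
    if prior is None:
        prior = SpikeSlabPrior.for_problem(problem)
    rng = np.random.default_rng(seed)
    P = problem.n_penalized
    d = problem.col_norms2
    active = d > 1e-12 * max(float(d.max()), 1.0)
    if not active.all():
        warnings.warn(
            f"{int((~active).sum())} zero-variance penalized columns excluded "
            "from inference (inclusion probability forced to 0)",
            stacklevel=2,
        )
    p = np.where(active, rng.uniform(0.05, 0.95, size=P), 0.0)
    mu = np.zeros(P)

    if fixed is not None:
        e_tau = 1.0 / fixed.sigma_e2
        e_kappa = 1.0 / fixed.sigma_beta2
        tb_mean, tb_elog, tb_elog1m, tb_lognorm = (
            fixed.p_nonzero,
            math.log(fixed.p_nonzero),
            math.log1p(-fixed.p_nonzero),
            0.0,
        )
        ba, bb = prior.beta_a, prior.beta_b
    else:
        e_tau = prior.gamma_shape / prior.gamma_rate
        e_kappa = e_tau
        tb = truncated_beta_moments(prior.beta_a, prior.beta_b, prior.bound)
        tb_mean, tb_elog, tb_elog1m, tb_lognorm = tb.mean, tb.elog, tb.elog1m, tb.log_norm
        ba, bb = prior.beta_a, prior.beta_b

    s2 = np.where(active, 1.0 / (e_tau * d + e_kappa), 1.0)
    return VariationalState(
        p=p,
        mu=mu,
        s2=s2,
        active=active,
        beta_a=ba,
        beta_b=bb,
        bound=prior.bound,
        theta_mean=tb_mean,
        elog_theta=tb_elog,
        elog_1mtheta=tb_elog1m,
        log_norm_theta=tb_lognorm,
        tau_shape=prior.gamma_shape,
        tau_rate=prior.gamma_rate,
        kappa_shape=prior.gamma_shape,
        kappa_rate=prior.gamma_rate,
        intercept=0.0,
        alpha=np.zeros(problem.n_covariates),
        seed=None if seed is None else int(np.random.default_rng(seed).integers(2**31)),
        fixed=fixed,
    )


# ---------------------------------------------------------------------------
# single-block updates (public contract; fit_vb uses the fast kernel below)

def _offset(state: VariationalState, problem: RegressionProblem) -> np.ndarray:
    off = np.full(problem.n, state.intercept)
    if problem.n_covariates:
        off += problem.T @ state.alpha
    return off


def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-min(x, 700.0)))
    z = math.exp(max(x, -700.0))
    return z / (1.0 + z)


def update_feature(
    state: VariationalState, problem: RegressionProblem, j: int
) -> VariationalState:
    """Exact coordinate update of the j-th feature factor, all else fixed.

    s2_j  = (<tau> d_j + <kappa>)^-1 with d_j the squared norm of column j,
    mu_j  = <tau> s2_j (w_j . r_{-j}) with r_{-j} the residual excluding
            feature j's expected contribution,
    logit p_j = <log theta - log(1-theta)> + (<log kappa> + log s2_j)/2
                + mu_j^2 / (2 s2_j).
    """
    if not state.active[j]:
        return state
    w_j = problem.W[:, j]
    d_j = float(w_j @ w_j)
    pm = state.p * state.mu
    r = problem.y - _offset(state, problem) - problem.W @ pm
    c_j = float(w_j @ r) + pm[j] * d_j
    e_tau, e_kappa = state.e_tau, state.e_kappa
    s2_j = 1.0 / (e_tau * d_j + e_kappa)
    mu_j = e_tau * s2_j * c_j
    logit = (
        state.elog_theta
        - state.elog_1mtheta
        + 0.5 * (state.e_log_kappa + math.log(s2_j))
        + mu_j * mu_j / (2.0 * s2_j)
    )
    if not (math.isfinite(mu_j) and math.isfinite(logit)):
        raise FloatingPointError(f"non-finite update for feature {j}")
    state.s2[j] = s2_j
    state.mu[j] = mu_j
    state.p[j] = _sigmoid(logit)
    return state


def _expected_rss(state: VariationalState, problem: RegressionProblem) -> float:
    """E||y - offset - W b||^2 under the factorized posterior."""
    pm = state.p * state.mu
    r = problem.y - _offset(state, problem) - problem.W @ pm
    var_b = state.p * (state.mu**2 + state.s2) - pm**2
    return float(r @ r + problem.col_norms2 @ var_b)


def update_hyperparameters(
    state: VariationalState,
    problem: RegressionProblem,
    prior: SpikeSlabPrior,
) -> VariationalState:
    """Exact updates of q(theta), q(sigma_beta^-2), q(sigma_e^-2)."""
    if state.fixed is not None:
        return state
    act = state.active
    sp = float(state.p[act].sum())
    sb = float((state.p[act] * (state.mu[act] ** 2 + state.s2[act])).sum())
    P_act = int(act.sum())

    state.beta_a = prior.beta_a + sp
    state.beta_b = prior.beta_b + P_act - sp
    tb = truncated_beta_moments(state.beta_a, state.beta_b, prior.bound)
    state.theta_mean, state.elog_theta = tb.mean, tb.elog
    state.elog_1mtheta, state.log_norm_theta = tb.elog1m, tb.log_norm

    state.kappa_shape = prior.gamma_shape + 0.5 * sp
    state.kappa_rate = prior.gamma_rate + 0.5 * sb
    state.tau_shape = prior.gamma_shape + 0.5 * problem.n
    state.tau_rate = prior.gamma_rate + 0.5 * _expected_rss(state, problem)
    if min(state.kappa_shape, state.kappa_rate, state.tau_shape, state.tau_rate) <= 0:
        raise FloatingPointError("degenerate Gamma hyper-posterior")
    return state


def update_unpenalized(
    state: VariationalState, problem: RegressionProblem
) -> VariationalState:
    """Least-squares update of the intercept and covariate effects on the
    residual after removing the expected penalized fit; this maximizes the
    lower bound over the non-random parameters."""
    target = problem.y - problem.W @ (state.p * state.mu)
    D = np.hstack([np.ones((problem.n, 1)), problem.T])
    coef, _, rank, _ = np.linalg.lstsq(D, target, rcond=None)
    if rank < D.shape[1]:
        logger.warning(
            "rank-deficient unpenalized design (rank %d < %d); minimum-norm solution used",
            rank,
            D.shape[1],
        )
    state.intercept = float(coef[0])
    state.alpha = coef[1:]
    return state


def lower_bound(
    state: VariationalState,
    problem: RegressionProblem,
    prior: SpikeSlabPrior,
) -> float:
    """Evidence lower bound: E_q[log p(y, b, theta, kappa, tau)] - E_q[log q].

    All terms in natural log. With fixed hyperparameters the hyper-KL terms
    are constants and omitted.
    """
    n = problem.n
    act = state.active
    e_tau, e_log_tau = state.e_tau, state.e_log_tau
    e_kappa, e_log_kappa = state.e_kappa, state.e_log_kappa

    L = 0.5 * n * (e_log_tau - _LOG_2PI) - 0.5 * e_tau * _expected_rss(state, problem)

    p, mu, s2 = state.p[act], state.mu[act], state.s2[act]
    slab = (
        state.elog_theta
        + 0.5 * (e_log_kappa - _LOG_2PI)
        - 0.5 * e_kappa * (mu**2 + s2)
        + 0.5 * (1.0 + _LOG_2PI + np.log(s2))
    )
    L += float((p * slab).sum() + (1.0 - p).sum() * state.elog_1mtheta)
    L -= float(xlogy(p, p).sum() + xlogy(1.0 - p, 1.0 - p).sum())

    if state.fixed is None:
        prior_tb = truncated_beta_moments(prior.beta_a, prior.beta_b, prior.bound)
        L += (prior.beta_a - state.beta_a) * state.elog_theta
        L += (prior.beta_b - state.beta_b) * state.elog_1mtheta
        L += state.log_norm_theta - prior_tb.log_norm

        a0, b0 = prior.gamma_shape, prior.gamma_rate
        for a, b, e_x, e_log_x in (
            (state.kappa_shape, state.kappa_rate, e_kappa, e_log_kappa),
            (state.tau_shape, state.tau_rate, e_tau, e_log_tau),
        ):
            L += a0 * math.log(b0) - gammaln(a0) + (a0 - 1.0) * e_log_x - b0 * e_x
            L -= a * math.log(b) - gammaln(a) + (a - 1.0) * e_log_x - a
    if not math.isfinite(L):
        raise FloatingPointError("non-finite lower bound")
    return float(L)


# ---------------------------------------------------------------------------
# full fit

def _sweep_kernel(
    order: np.ndarray,
    WtR: np.ndarray,
    G: np.ndarray,
    d: np.ndarray,
    p: np.ndarray,
    mu: np.ndarray,
    s2: np.ndarray,
    e_tau: float,
    base_logit: np.ndarray,
) -> None:
    """One pass of exact feature updates, maintaining WtR = W^T(y_adj - W(p*mu)).

    ``base_logit[j]`` carries the residual-independent part of the inclusion
    logit; s2 is constant within a sweep because the precision moments only
    change at the hyperparameter step. Finiteness is verified once at the end
    of the pass (cheaper than a per-feature guard).
    """
    exp = math.exp
    for j in order:
        pm_old = p[j] * mu[j]
        s2j = s2[j]
        m = e_tau * s2j * (WtR[j] + pm_old * d[j])
        logit = base_logit[j] + m * m / (2.0 * s2j)
        if logit >= 0.0:
            pj = 1.0 / (1.0 + exp(-logit if logit < 700.0 else -700.0))
        else:
            z = exp(logit if logit > -700.0 else -700.0)
            pj = z / (1.0 + z)
        mu[j] = m
        p[j] = pj
        delta = pj * m - pm_old
        if delta != 0.0:
            daxpy(G[j], WtR, a=-delta)
    if not (np.isfinite(WtR).all() and np.isfinite(mu[order]).all()):
        bad = order[~np.isfinite(mu[order])]
        raise FloatingPointError(
            f"non-finite update for feature(s) {bad[:5].tolist() or order[:0].tolist()}"
        )


def fit_vb(
    problem: RegressionProblem,
    prior: SpikeSlabPrior | None = None,
    seed: int | None = 0,
    max_sweeps: int = 500,
    rel_tol: float = 1e-6,
    fixed: FixedHyperparameters | None = None,
    track_elbo: bool = False,
) -> VariationalState:
    """Run coordinate-ascent VB to convergence from one random start.

    Features are updated in a fresh random permutation each sweep, followed
    by the hyperparameter and unpenalized-effect updates. Stops when the
    relative lower-bound change |dL| / (1 + |L|) falls below ``rel_tol`` or
    after ``max_sweeps`` sweeps (non-convergence sets the flag, not an error).
    """
    if prior is None:
        prior = SpikeSlabPrior.for_problem(problem)
    rng = np.random.default_rng(seed)
    state = init_state(problem, prior, seed=rng.integers(2**31), fixed=fixed)

    W, y = problem.W, problem.y
    G = W.T @ W
    d = np.diag(G).copy()
    act_idx = np.flatnonzero(state.active)
    y_adj = y - _offset(state, problem)
    WtR = W.T @ y_adj - G @ (state.p * state.mu)

    history: list[float] = []
    last_L = -np.inf
    dL = np.inf
    for sweep in range(1, max_sweeps + 1):
        e_tau, e_kappa = state.e_tau, state.e_kappa
        s2 = state.s2
        s2[act_idx] = 1.0 / (e_tau * d[act_idx] + e_kappa)
        base = np.full_like(s2, -np.inf)
        base[act_idx] = (
            state.elog_theta
            - state.elog_1mtheta
            + 0.5 * (state.e_log_kappa + np.log(s2[act_idx]))
        )
        order = rng.permutation(act_idx)
        _sweep_kernel(order, WtR, G, d, state.p, state.mu, s2, e_tau, base)

        update_hyperparameters(state, problem, prior)
        old_offset = _offset(state, problem)
        update_unpenalized(state, problem)
        new_offset = _offset(state, problem)
        if problem.n_covariates or abs(state.intercept) > 0:
            WtR -= W.T @ (new_offset - old_offset)

        if sweep % 50 == 0:  # bound floating-point drift
            WtR = W.T @ (y - new_offset) - G @ (state.p * state.mu)

        L = lower_bound(state, problem, prior)
        state.lower_bound = L
        state.n_sweeps = sweep
        if track_elbo:
            history.append(L)
        dL = abs(L - last_L) / (1.0 + abs(L))
        if math.isfinite(last_L) and dL < rel_tol:
            state.converged = True
            break
        last_L = L
    if not state.converged:
        logger.warning("VB did not converge in %d sweeps (relative dL %.3e)",
                       max_sweeps, dL)
    if track_elbo:
        state.elbo_trace = history  # type: ignore[attr-defined]
    state.validate()
    return state


# ---------------------------------------------------------------------------
# multi-restart Bayesian model averaging

@dataclass(frozen=True)
class RestartRecord:
    p: np.ndarray
    mu: np.ndarray
    lower_bound: float
    seed: int
    converged: bool


@dataclass(frozen=True)
class FitResult:
    """Restart-averaged posterior inclusion probabilities.

    Restarts are weighted by exp(L_r - max L) normalized, i.e. the relative
    evidence of each mode under the lower bound; p_hat is the convex
    combination of per-restart inclusion probabilities and ``effect`` the
    matching expected coefficient sum_r w_r p_j^(r) mu_j^(r).
    """

    restarts: list[RestartRecord] = field(repr=False)
    weights: np.ndarray
    p_hat: np.ndarray
    effect: np.ndarray

    @property
    def n_restarts(self) -> int:
        return len(self.restarts)

    def to_frame(self, feature_names: list[str] | None = None):
        """Per-feature table: id, averaged inclusion probability, weighted
        expected effect. Serialize with ``.to_csv(path, sep='\\t')``."""
        import pandas as pd

        names = feature_names or [f"f{j}" for j in range(len(self.p_hat))]
        return pd.DataFrame(
            {"feature": names, "p_hat": self.p_hat, "effect": self.effect}
        )

    def restarts_frame(self):
        """Companion table with each restart's seed and lower bound."""
        import pandas as pd

        return pd.DataFrame(
            {
                "restart": range(len(self.restarts)),
                "seed": [r.seed for r in self.restarts],
                "lower_bound": [r.lower_bound for r in self.restarts],
                "weight": self.weights,
                "converged": [r.converged for r in self.restarts],
            }
        )


def fit_restarts(
    problem: RegressionProblem,
    prior: SpikeSlabPrior | None = None,
    n_restarts: int = 50,
    master_seed: int = 0,
    max_sweeps: int = 500,
    rel_tol: float = 1e-6,
    fixed: FixedHyperparameters | None = None,
) -> FitResult:
    """Run ``n_restarts`` VB fits from distinct seeds and average by evidence."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if prior is None:
        prior = SpikeSlabPrior.for_problem(problem)
    seeds = [int(s.generate_state(1)[0]) for s in SeedSequence(master_seed).spawn(n_restarts)]
    records = []
    for s in seeds:
        st = fit_vb(problem, prior, seed=s, max_sweeps=max_sweeps, rel_tol=rel_tol,
                    fixed=fixed)
        records.append(
            RestartRecord(p=st.p.copy(), mu=st.mu.copy(), lower_bound=st.lower_bound,
                          seed=s, converged=st.converged)
        )
    Ls = np.array([r.lower_bound for r in records])
    if not np.isfinite(Ls).any():
        raise FloatingPointError("no restart produced a finite lower bound")
    w = np.exp(Ls - Ls.max())
    w /= w.sum()
    p_hat = np.clip(sum(wi * r.p for wi, r in zip(w, records)), 0.0, 1.0)
    effect = sum(wi * r.p * r.mu for wi, r in zip(w, records))
    return FitResult(restarts=records, weights=w, p_hat=p_hat, effect=effect)
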