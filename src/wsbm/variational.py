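"""Mean-field variational EM machinery for the weighted SBM.

The posterior over block labels is approximated by a product of per-vertex
multinomials with probability matrix ``tau`` (n x Q).  Coordinate ascent
alternates a damped fixed-point update of ``tau`` with closed-form updates
of the block proportions and edge probabilities and the closed-form
Ye-Chen estimators of the gamma shape/rate.

Everything here works on plain arrays; the model/results surface is in
:mod:`wsbm.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .graph import WeightedGraph
from .params import ParameterBox, WSBMParams

__all__ = [
    "VariationalPosterior",
    "SufficientStats",
    "FitConfig",
    "EmptyBlockError",
    "sufficient_stats",
    "elbo",
    "update_tau",
    "update_theta_pi",
    "ye_chen_update",
    "initial_tau_spectral",
    "initial_tau_random",
]

TAU_FLOOR = 1e-12
W_EPS = 1e-6  # tau-weighted edge mass below which a cell counts as empty


class EmptyBlockError(RuntimeError):
    """A block lost all posterior mass during fitting."""


@dataclass(frozen=True)
class VariationalPosterior:
    """n x Q membership-probability matrix; rows on the simplex."""

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 2:
            raise ValueError("tau must be an n x Q matrix")
        if np.any(tau < 0) or np.any(tau > 1):
            raise ValueError("tau entries must lie in [0, 1]")
        if np.any(np.abs(tau.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("tau rows must sum to 1")
        object.__setattr__(self, "tau", tau)

    @property
    def n(self) -> int:
        return self.tau.shape[0]

    @property
    def Q(self) -> int:
        return self.tau.shape[1]

    def hard_assignment(self) -> np.ndarray:
        """Row-wise argmax labels (ties go to the lowest block index)."""
        return np.argmax(self.tau, axis=1)


@dataclass(frozen=True)
class SufficientStats:
    """tau-weighted edge statistics per block pair (existing edges only).

    ``W`` sums ``tau_iq tau_jl``, ``U`` additionally weights by ``Y_ij``,
    ``V`` by ``log Y_ij`` and ``S`` by ``Y_ij log Y_ij``.
    """

    W: np.ndarray
    U: np.ndarray
    V: np.ndarray
    S: np.ndarray


def _astau(tau) -> np.ndarray:
    if isinstance(tau, VariationalPosterior):
        return tau.tau
    return np.asarray(tau, dtype=float)


def _weight_products(graph: WeightedGraph) -> tuple[np.ndarray, np.ndarray]:
    """(X*logY, Y*logY) with zeros off the support, cached on the graph."""
    try:
        return graph._XlogY, graph._YlogY  # type: ignore[attr-defined]
    except AttributeError:
        pass
    XlogY = graph.log_weights()
    YlogY = graph.Y * XlogY
    object.__setattr__(graph, "_XlogY", XlogY)
    object.__setattr__(graph, "_YlogY", YlogY)
    return XlogY, YlogY


def sufficient_stats(graph: WeightedGraph, tau) -> SufficientStats:
    """Compute the four Q x Q tau-weighted edge-statistic matrices."""
    tau = _astau(tau)
    XlogY, YlogY = _weight_products(graph)
    W = tau.T @ graph.X @ tau
    U = tau.T @ graph.Y @ tau
    V = tau.T @ XlogY @ tau
    S = tau.T @ YlogY @ tau
    return SufficientStats(W=W, U=U, V=V, S=S)


def _gamma_cell_objective(
    alpha: np.ndarray, beta: np.ndarray, stats: SufficientStats
) -> np.ndarray:
    """Per-cell gamma contribution to the variational objective."""
    return (
        stats.W * (alpha * np.log(beta) - gammaln(alpha))
        + (alpha - 1.0) * stats.V
        - beta * stats.U
    )


def elbo(graph: WeightedGraph, tau, params: WSBMParams) -> float:
    """Variational lower bound J on the observed-data log-likelihood.

    ``J = sum_{i!=j, q, l} tau_iq tau_jl [log b(X_ij; pi_ql) + X_ij log
    f(Y_ij; alpha_ql, beta_ql)] - sum_{i,q} tau_iq (log tau_iq - log
    theta_q)`` with the convention ``0 log 0 = 0``.
    """
    tau = _astau(tau)
    stats = sufficient_stats(graph, tau)
    s = tau.sum(axis=0)
    pairs = np.outer(s, s) - tau.T @ tau  # sum over i != j of tau_iq tau_jl
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_1mpi = np.log1p(-params.pi)
    bern = stats.W * log_pi + (pairs - stats.W) * log_1mpi
    # 0 * -inf from pi in {0, 1} with no mass on the contradicting outcome
    bern = np.where(
        (stats.W == 0) & np.isneginf(log_pi), 0.0, bern
    )
    bern = np.where(
        (pairs - stats.W == 0) & np.isneginf(log_1mpi), 0.0, bern
    )
    gam = _gamma_cell_objective(params.alpha, params.beta, stats)
    tau_safe = np.maximum(tau, TAU_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_theta = np.log(params.theta)
        per_entry = tau * (log_theta[None, :] - np.log(tau_safe))
    mixing = np.sum(np.where(tau > 0, per_entry, 0.0))  # 0 log 0 = 0
    return float(bern.sum() + gam.sum() + mixing)


def _log_field(graph: WeightedGraph, tau: np.ndarray, params: WSBMParams) -> np.ndarray:
    """n x Q matrix of log-domain messages for the tau fixed point.

    Entry (i, q) is the expected complete-data log-likelihood contribution
    of assigning vertex i to block q, holding the other rows of tau fixed.
    Both edge directions at i contribute (the graph is directed).
    """
    X, Y = graph.X, graph.Y
    XlogY, _ = _weight_products(graph)
    pi, alpha, beta = params.pi, params.alpha, params.beta
    c0 = np.log1p(-pi)
    c1 = np.log(pi) - c0 + alpha * np.log(beta) - gammaln(alpha)
    c2 = alpha - 1.0
    c3 = beta

    T = tau.sum(axis=0)[None, :] - tau  # sum over j != i of tau_jl
    A_out = X @ tau
    B_out = XlogY @ tau
    C_out = Y @ tau
    A_in = X.T @ tau
    B_in = XlogY.T @ tau
    C_in = Y.T @ tau

    F = (
        T @ (c0.T + c0)
        + A_out @ c1.T
        + B_out @ c2.T
        - C_out @ c3.T
        + A_in @ c1
        + B_in @ c2
        - C_in @ c3
    )
    return F


def _normalize_rows(logits: np.ndarray) -> np.ndarray:
    """Softmax rows with max-subtraction, floored at TAU_FLOOR."""
    m = logits.max(axis=1, keepdims=True)
    t = np.exp(logits - m)
    t /= t.sum(axis=1, keepdims=True)
    t = np.maximum(t, TAU_FLOOR)
    t /= t.sum(axis=1, keepdims=True)
    return t


def update_tau(
    graph: WeightedGraph,
    tau,
    params: WSBMParams,
    damping: float = 0.5,
    max_inner: int = 50,
    tol: float = 1e-6,
):
    """Iterate the mean-field fixed point for the membership matrix.

    Each sweep recomputes ``tau_iq proportional to theta_q exp(F_iq)`` with
    ``F`` the log-domain message field, then damps: ``tau_new = (1 -
    damping) * proposed + damping * old``.  Sweeps stop when the largest
    absolute row change falls below ``tol`` or after ``max_inner`` sweeps.
    """
    tau = _astau(tau).copy()
    with np.errstate(divide="ignore"):
        log_theta = np.log(params.theta)[None, :]
    for _ in range(max_inner):
        F = _log_field(graph, tau, params)
        if not np.isfinite(F).all():
            i, q = np.argwhere(~np.isfinite(F))[0]
            raise FloatingPointError(
                f"non-finite log-weight in tau update at vertex {i}, block {q}"
            )
        proposed = _normalize_rows(log_theta + F)
        new = (1.0 - damping) * proposed + damping * tau
        change = np.max(np.abs(new - tau))
        tau = new
        if change < tol:
            break
    return VariationalPosterior(tau=tau)


def update_theta_pi(
    graph: WeightedGraph, tau, zeta: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form updates of block proportions and edge probabilities.

    ``theta_q`` is the mean membership; ``pi_ql`` the tau-weighted edge
    frequency, clipped into ``[zeta, 1 - zeta]``.  A vanishing denominator
    (a block with no pair mass) raises :class:`EmptyBlockError`.
    """
    tau = _astau(tau)
    n = tau.shape[0]
    theta = tau.sum(axis=0) / n
    s = tau.sum(axis=0)
    pairs = np.outer(s, s) - tau.T @ tau
    if np.any(pairs <= 0):
        q, l = np.argwhere(pairs <= 0)[0]
        raise EmptyBlockError(
            f"no pair mass for block pair ({q}, {l}); a block is empty"
        )
    W = tau.T @ graph.X @ tau
    pi = np.clip(W / pairs, zeta, 1.0 - zeta)
    return theta, pi


def ye_chen_update(
    stats: SufficientStats, box: ParameterBox | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Closed-form gamma shape/rate estimates from the edge statistics.

    Per cell, with ``D = W S - V U``: ``alpha = W U / D`` and ``beta =
    W^2 / D``, clipped into the compact box.  Degenerate cells are handled
    in-band and flagged:

    - ``empty``: ``W < 1e-6`` -- the cell receives the global estimate
      pooled over all edges;
    - ``degenerate``: ``D <= 0`` (zero or negative weighted log-variance,
      e.g. all weights identical) -- the shape saturates at the box upper
      bound with the rate matched to the cell mean;
    - ``clipped``: the raw estimate fell outside the box.
    """
    if box is None:
        box = ParameterBox()
    W, U, V, S = stats.W, stats.U, stats.V, stats.S
    D = W * S - V * U

    # pooled fallback over all edges
    Wg, Ug, Vg, Sg = W.sum(), U.sum(), V.sum(), S.sum()
    Dg = Wg * Sg - Vg * Ug
    if Wg >= W_EPS and Dg > 0:
        a_glob = Wg * Ug / Dg
        b_glob = Wg**2 / Dg
    else:
        a_glob, b_glob = 1.0, 1.0

    empty = W < W_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(D > 0, W * U / D, np.nan)
        beta = np.where(D > 0, W**2 / D, np.nan)

    degenerate = (~empty) & ~(D > 0)
    if degenerate.any():
        mean = np.where(W > 0, U / np.maximum(W, W_EPS), 1.0)
        alpha = np.where(degenerate, box.alpha_C, alpha)
        beta = np.where(degenerate, box.alpha_C / np.maximum(mean, 1e-300), beta)
    alpha = np.where(empty, a_glob, alpha)
    beta = np.where(empty, b_glob, beta)

    alpha_clipped = np.clip(alpha, box.alpha_c, box.alpha_C)
    beta_clipped = np.clip(beta, box.beta_c, box.beta_C)
    clipped = (alpha_clipped != alpha) | (beta_clipped != beta)
    flags = {"empty": empty, "degenerate": degenerate, "clipped": clipped}
    return alpha_clipped, beta_clipped, flags


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the variational EM loop.

    ``restarts`` counts initializations (one spectral-style k-means start
    plus random-multinomial restarts); ``tol`` is the relative ELBO change
    declaring outer convergence; the inner fixed point is damped and
    stopped by ``inner_tol``/``max_inner``.
    """

    restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-8
    damping: float = 0.5
    max_inner: int = 50
    inner_tol: float = 1e-6
    box: ParameterBox = field(default_factory=ParameterBox)
    init: str = "spectral"  # first restart; the rest are random

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.init not in ("spectral", "random"):
            raise ValueError("init must be 'spectral' or 'random'")


def _soften_labels(labels: np.ndarray, Q: int, confidence: float = 0.9) -> np.ndarray:
    n = labels.shape[0]
    if Q == 1:
        return np.ones((n, 1))
    tau = np.full((n, Q), (1.0 - confidence) / (Q - 1))
    tau[np.arange(n), labels] = confidence
    return tau


def initial_tau_spectral(graph: WeightedGraph, Q: int, seed: int) -> np.ndarray:
    """k-means initialization on edge-pattern features.

    Rows of ``[X | X*log1p(Y)]`` concatenated with the transposed blocks
    (so in- and out-profiles both inform the clustering) are reduced to a
    few principal directions and clustered; the hard labels are softened
    to 0.9 mass on the assigned block.
    """
    from sklearn.cluster import KMeans
    from sklearn.utils.extmath import randomized_svd

    n = graph.n
    if Q == 1:
        return np.ones((n, 1))
    if n <= Q:
        return initial_tau_random(np.random.default_rng(seed), n, Q)
    Xw = graph.X * np.log1p(graph.Y)
    feats = np.hstack([graph.X, Xw, graph.X.T, Xw.T])
    d = min(max(2 * Q, 4), n - 1, feats.shape[1])
    U_, s_, _ = randomized_svd(feats, n_components=d, random_state=seed % (2**31))
    emb = U_ * s_
    km = KMeans(n_clusters=Q, n_init=10, random_state=seed % (2**31))
    labels = km.fit_predict(emb)
    return _soften_labels(labels, Q)


def initial_tau_random(rng: np.random.Generator, n: int, Q: int) -> np.ndarray:
    """Random membership rows drawn from a flat Dirichlet."""
    if Q == 1:
        return np.ones((n, 1))
    tau = rng.dirichlet(np.ones(Q), size=n)
    tau = np.maximum(tau, TAU_FLOOR)
    return tau / tau.sum(axis=1, keepdims=True)


def _coordinate_ascent(
    graph: WeightedGraph, Q: int, tau0: np.ndarray, config: FitConfig
) -> dict:
    """One restart of the variational EM loop from a given tau.

    Returns a dict with the final parameter set, tau, ELBO trace, and
    convergence/degeneracy flags.  The trace is non-decreasing up to
    roundoff by construction: the tau step backtracks toward the previous
    tau when the damped parallel update overshoots, and a Ye-Chen cell
    update is kept only when it does not lower that cell's objective
    contribution (the closed-form estimator is a moment-type estimator,
    not the exact argmax).
    """
    tau = tau0
    theta, pi = update_theta_pi(graph, tau, zeta=config.box.zeta)
    stats = sufficient_stats(graph, tau)
    alpha, beta, _ = ye_chen_update(stats, config.box)
    params = WSBMParams(theta=theta, pi=pi, alpha=alpha, beta=beta)
    J = elbo(graph, tau, params)
    trace = [J]
    converged = False
    n_iter = 0

    for it in range(1, config.max_iter + 1):
        n_iter = it
        proposed = update_tau(
            graph,
            tau,
            params,
            damping=config.damping,
            max_inner=config.max_inner,
            tol=config.inner_tol,
        ).tau
        # accept the tau move only if it improves J; backtrack otherwise
        J_new = elbo(graph, proposed, params)
        if J_new < J - 1e-10:
            step = proposed - tau
            for t in (0.5, 0.25, 0.125, 0.0625):
                cand = tau + t * step
                J_cand = elbo(graph, cand, params)
                if J_cand >= J - 1e-10:
                    proposed, J_new = cand, J_cand
                    break
            else:
                proposed, J_new = tau, J
        tau = proposed

        theta, pi = update_theta_pi(graph, tau, zeta=config.box.zeta)
        stats = sufficient_stats(graph, tau)
        a_new, b_new, _ = ye_chen_update(stats, config.box)
        obj_old = _gamma_cell_objective(params.alpha, params.beta, stats)
        obj_new = _gamma_cell_objective(a_new, b_new, stats)
        keep_new = obj_new >= obj_old - 1e-12
        alpha = np.where(keep_new, a_new, params.alpha)
        beta = np.where(keep_new, b_new, params.beta)
        params = WSBMParams(theta=theta, pi=pi, alpha=alpha, beta=beta)

        J_prev = J
        J = elbo(graph, tau, params)
        trace.append(J)
        if abs(J - J_prev) <= config.tol * (1.0 + abs(J_prev)):
            converged = True
            break

    degenerate = bool(np.min(params.theta) < config.box.gamma_min)
    return {
        "params": params,
        "tau": tau,
        "elbo": J,
        "trace": trace,
        "n_iter": n_iter,
        "converged": converged,
        "degenerate": degenerate,
    }
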