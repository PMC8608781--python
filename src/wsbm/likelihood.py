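"""Exact likelihood computations.

``complete_loglik`` evaluates the complete-data log-likelihood at a given
label vector; ``exact_loglik`` marginalises it over all Q^n allocations by
brute force and exists as a test oracle for tiny graphs only.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln, logsumexp

from .graph import WeightedGraph
from .params import BlockAssignment, WSBMParams

__all__ = [
    "gamma_logpdf",
    "complete_loglik",
    "complete_loglik_parts",
    "exact_loglik",
]

DEFAULT_ENUMERATION_CAP = 10**6


def gamma_logpdf(y, a, b):
    """Log density of Gamma(shape ``a``, rate ``b``) at ``y``.

    Evaluated in log space as ``(a-1) log y - b y + a log b - lgamma(a)``;
    the density itself is never formed, so large shapes stay finite.
    Inputs broadcast; all must be strictly positive.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma_logpdf requires y > 0")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("gamma_logpdf requires a > 0 and b > 0")
    out = (a - 1.0) * np.log(y) - b * y + a * np.log(b) - gammaln(a)
    return out if out.ndim else float(out)


def complete_loglik_parts(
    graph: WeightedGraph, z: BlockAssignment, params: WSBMParams
) -> tuple[float, float]:
    """Bernoulli and gamma components of the complete-data log-likelihood.

    The Bernoulli part is ``sum_{i!=j} X_ij log pi_{z_i z_j} + (1 - X_ij)
    log(1 - pi_{z_i z_j})``; the gamma part is ``sum_{i!=j} X_ij log
    f(Y_ij; alpha_{z_i z_j}, beta_{z_i z_j})``.  Edge probabilities of
    exactly 0 or 1 contradicted by an observation yield -inf, not an
    exception.
    """
    zz = z.z
    X, Y = graph.X, graph.Y
    n = graph.n
    off = ~np.eye(n, dtype=bool)
    P = params.pi[np.ix_(zz, zz)]
    with np.errstate(divide="ignore", invalid="ignore"):
        bern = np.where(X == 1.0, np.log(P), np.log1p(-P))
    bern_part = float(np.sum(np.where(off, bern, 0.0)))

    mask = (X == 1.0) & off
    if mask.any():
        A = params.alpha[np.ix_(zz, zz)][mask]
        B = params.beta[np.ix_(zz, zz)][mask]
        gamma_part = float(np.sum(gamma_logpdf(Y[mask], A, B)))
    else:
        gamma_part = 0.0
    return bern_part, gamma_part


def complete_loglik(
    graph: WeightedGraph, z: BlockAssignment, params: WSBMParams
) -> float:
    """Complete-data log-likelihood of (X, Y) at label vector ``z``."""
    bern, gam = complete_loglik_parts(graph, z, params)
    return bern + gam


def exact_loglik(
    graph: WeightedGraph,
    params: WSBMParams,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> float:
    """Observed-data log-likelihood by exhaustive enumeration.

    Sums ``exp(L1(z)) * prod_i theta_{z_i}`` over all Q^n allocations in
    lexicographic order with a log-sum-exp reduction.  Intended as a
    brute-force oracle: refuses if ``Q**n`` exceeds ``cap``.
    """
    n, Q = graph.n, params.Q
    if Q**n > cap:
        raise ValueError(
            f"enumeration over Q^n = {Q}^{n} allocations exceeds cap={cap}; "
            "exact_loglik is a brute-force oracle for tiny graphs only"
        )
    with np.errstate(divide="ignore"):
        log_theta = np.log(params.theta)
        log_pi = np.log(params.pi)
        log_1mpi = np.log1p(-params.pi)

    # per-pair Q x Q contribution tables: M[i][j][q, l] is the complete-data
    # term of edge slot (i, j) when z_i = q, z_j = l
    M = np.empty((n, n, Q, Q))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if graph.X[i, j] == 1.0:
                M[i, j] = log_pi + gamma_logpdf(
                    graph.Y[i, j], params.alpha, params.beta
                )
            else:
                M[i, j] = log_1mpi

    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    chunks = []
    it = itertools.product(range(Q), repeat=n)  # lexicographic order
    while True:
        block = list(itertools.islice(it, 65536))
        if not block:
            break
        Z = np.asarray(block)
        terms = log_theta[Z].sum(axis=1)
        for i, j in pairs:
            terms = terms + M[i, j][Z[:, i], Z[:, j]]
        chunks.append(logsumexp(terms))
    return float(logsumexp(np.asarray(chunks)))
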