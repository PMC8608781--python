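"""Parameter containers and model-assumption checks for the weighted SBM.

The model has ``Q`` latent blocks.  A directed graph on ``n`` vertices is
generated by drawing block labels i.i.d. from ``theta``, edge indicators
``X_ij ~ Bernoulli(pi[z_i, z_j])`` for every ordered pair ``i != j``, and,
on existing edges, weights ``Y_ij ~ Gamma(shape=alpha[z_i, z_j],
rate=beta[z_i, z_j])``.

The gamma distribution is parameterised by shape and **rate** throughout
(density ``y^(a-1) e^(-b y) b^a / Gamma(a)``), not shape/scale.  Block and
vertex indices are 0-based in memory; file formats and reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WSBMParams",
    "ParameterBox",
    "BlockAssignment",
    "AssumptionReport",
    "check_assumptions",
    "check_block_proportions",
    "ValidationError",
]

_ATOL = 1e-10


class ValidationError(ValueError):
    """An invariant of a model object is violated; the message names it."""


@dataclass(frozen=True)
class WSBMParams:
    """Full parameter set (theta, pi, alpha, beta) for a Q-block model.

    Parameters
    ----------
    theta : (Q,) array
        Block proportions; nonnegative, summing to 1.
    pi : (Q, Q) array
        Edge probabilities between (source block, target block) pairs.
    alpha, beta : (Q, Q) array
        Gamma shape and rate of the weight distribution per block pair;
        strictly positive.
    """

    theta: np.ndarray
    pi: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        Q = theta.shape[0]
        pi = np.asarray(self.pi, dtype=float).reshape(Q, Q)
        alpha = np.asarray(self.alpha, dtype=float).reshape(Q, Q)
        beta = np.asarray(self.beta, dtype=float).reshape(Q, Q)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        if np.any(theta < -_ATOL):
            raise ValidationError("theta entries must be nonnegative")
        if abs(theta.sum() - 1.0) > _ATOL:
            raise ValidationError(
                f"theta must sum to 1 (got {theta.sum():.12g})"
            )
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValidationError("pi entries must lie in [0, 1]")
        if np.any(alpha <= 0):
            raise ValidationError("alpha entries must be strictly positive")
        if np.any(beta <= 0):
            raise ValidationError("beta entries must be strictly positive")

    @property
    def Q(self) -> int:
        return self.theta.shape[0]

    def permuted(self, sigma: np.ndarray) -> "WSBMParams":
        """Return the parameter set with blocks relabeled by ``sigma``.

        ``sigma`` maps old block q to new block ``sigma[q]``; the returned
        object satisfies ``new.pi[sigma[q], sigma[l]] == self.pi[q, l]``.
        """
        sigma = np.asarray(sigma)
        inv = np.argsort(sigma)
        return WSBMParams(
            theta=self.theta[inv],
            pi=self.pi[np.ix_(inv, inv)],
            alpha=self.alpha[np.ix_(inv, inv)],
            beta=self.beta[np.ix_(inv, inv)],
        )

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "theta": self.theta.tolist(),
            "pi": self.pi.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WSBMParams":
        p = cls(
            theta=np.asarray(d["theta"], dtype=float),
            pi=np.asarray(d["pi"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
        )
        if "Q" in d and int(d["Q"]) != p.Q:
            raise ValidationError(
                f"declared Q={d['Q']} does not match theta length {p.Q}"
            )
        return p


@dataclass(frozen=True)
class ParameterBox:
    """Compact box constraining the gamma parameters during estimation.

    The gamma density at fixed mean diverges as the shape grows (Stirling
    argument), so unconstrained likelihood maximisation degenerates; all
    fitted shapes/rates are clipped into ``[alpha_c, alpha_C]`` x
    ``[beta_c, beta_C]``.  ``zeta`` keeps edge probabilities away from
    {0, 1} and ``gamma_min`` is the minimum admissible block proportion.
    """

    alpha_c: float = 1e-3
    alpha_C: float = 1e3
    beta_c: float = 1e-3
    beta_C: float = 1e3
    zeta: float = 1e-6
    gamma_min: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.alpha_c < self.alpha_C < np.inf):
            raise ValidationError("need 0 < alpha_c < alpha_C < inf")
        if not (0 < self.beta_c < self.beta_C < np.inf):
            raise ValidationError("need 0 < beta_c < beta_C < inf")
        if not (0 < self.zeta < 0.5):
            raise ValidationError("need 0 < zeta < 1/2")
        if not (0 < self.gamma_min < 1):
            raise ValidationError("need 0 < gamma_min < 1")


@dataclass(frozen=True)
class BlockAssignment:
    """Latent block labels for n vertices, entries in {0, ..., Q-1}."""

    z: np.ndarray
    Q: int

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.int64)
        object.__setattr__(self, "z", z)
        if self.Q < 1:
            raise ValidationError("Q must be >= 1")
        if z.ndim != 1:
            raise ValidationError("z must be a 1-d label vector")
        if z.size and (z.min() < 0 or z.max() >= self.Q):
            raise ValidationError("labels must lie in {0, ..., Q-1}")

    @property
    def n(self) -> int:
        return self.z.shape[0]

    def counts(self) -> np.ndarray:
        """Class sizes N_q = |{i : z_i = q}|."""
        return np.bincount(self.z, minlength=self.Q)

    def onehot(self) -> np.ndarray:
        tau = np.zeros((self.n, self.Q))
        tau[np.arange(self.n), self.z] = 1.0
        return tau


@dataclass
class AssumptionReport:
    """Outcome of the identifiability/regularity checks on a parameter set.

    ``a1``/``a5`` are the separability conditions (no two blocks share the
    same connectivity profile, resp. weight-distribution profile); ``a2``,
    ``a3``, ``a6`` are the box conditions on pi, theta and (alpha, beta).
    Violating block pairs (0-based) are listed per failed check.
    """

    a1: bool
    a2: bool
    a3: bool
    a5: bool
    a6: bool
    a1_pairs: list = field(default_factory=list)
    a2_pairs: list = field(default_factory=list)
    a3_blocks: list = field(default_factory=list)
    a5_pairs: list = field(default_factory=list)
    a6_pairs: list = field(default_factory=list)

    def all_hold(self) -> bool:
        return self.a1 and self.a2 and self.a3 and self.a5 and self.a6


def check_assumptions(
    params: WSBMParams, box: ParameterBox | None = None
) -> AssumptionReport:
    """Check the separability and box assumptions on a parameter set.

    Separability of blocks q != q' requires some l with ``pi[q,l] !=
    pi[q',l]`` or ``pi[l,q] != pi[l,q']`` (and the analogue for the
    (alpha, beta) pairs); the box conditions require ``pi`` inside
    ``[zeta, 1-zeta]``, ``theta`` inside ``[gamma_min, 1-gamma_min]`` and
    (alpha, beta) inside the compact box.
    """
    if box is None:
        box = ParameterBox()
    Q = params.Q
    pi, al, be, th = params.pi, params.alpha, params.beta, params.theta

    a1_pairs = []
    a5_pairs = []
    for q in range(Q):
        for qp in range(q + 1, Q):
            pi_same = np.array_equal(pi[q], pi[qp]) and np.array_equal(
                pi[:, q], pi[:, qp]
            )
            if pi_same:
                a1_pairs.append((q, qp))
            ab_same = (
                np.array_equal(al[q], al[qp])
                and np.array_equal(be[q], be[qp])
                and np.array_equal(al[:, q], al[:, qp])
                and np.array_equal(be[:, q], be[:, qp])
            )
            if ab_same:
                a5_pairs.append((q, qp))

    bad2 = np.argwhere((pi < box.zeta) | (pi > 1 - box.zeta))
    bad3 = np.argwhere((th < box.gamma_min) | (th > 1 - box.gamma_min))
    bad6 = np.argwhere(
        (al < box.alpha_c)
        | (al > box.alpha_C)
        | (be < box.beta_c)
        | (be > box.beta_C)
    )

    return AssumptionReport(
        a1=not a1_pairs,
        a2=bad2.size == 0,
        a3=bad3.size == 0,
        a5=not a5_pairs,
        a6=bad6.size == 0,
        a1_pairs=a1_pairs,
        a2_pairs=[tuple(ix) for ix in bad2],
        a3_blocks=[int(ix[0]) for ix in bad3],
        a5_pairs=a5_pairs,
        a6_pairs=[tuple(ix) for ix in bad6],
    )


def check_block_proportions(
    assignment: BlockAssignment, gamma_min: float
) -> bool:
    """Empirical analogue of the minimum-proportion condition.

    True iff every realized class proportion ``N_q/n`` is at least
    ``gamma_min``.
    """
    if assignment.n == 0:
        return False
    return bool((assignment.counts() / assignment.n >= gamma_min).all())
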