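"""Generative sampler for the weighted stochastic block model."""

from __future__ import annotations

import numpy as np

from .graph import WeightedGraph
from .params import BlockAssignment, WSBMParams

__all__ = ["sample_wsbm"]


def sample_wsbm(
    params: WSBMParams,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> tuple[WeightedGraph, BlockAssignment]:
    """Draw one directed weighted graph from the model.

    Labels are i.i.d. multinomial(theta); each ordered pair ``i != j``
    carries an edge with probability ``pi[z_i, z_j]`` and, if present, a
    Gamma(shape ``alpha[z_i, z_j]``, rate ``beta[z_i, z_j]``) weight.

    For reproducibility the weight field is drawn for every ordered pair
    and then masked to the realized edges, so the draw is a deterministic
    function of the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    z = rng.choice(params.Q, size=n, p=params.theta)
    P = params.pi[np.ix_(z, z)]
    X = (rng.random((n, n)) < P).astype(float)
    np.fill_diagonal(X, 0.0)
    shape = params.alpha[np.ix_(z, z)]
    scale = 1.0 / params.beta[np.ix_(z, z)]
    draws = rng.gamma(shape=shape, scale=scale)
    # very small shapes can underflow to exactly 0; keep edge weights positive
    Y = np.maximum(draws, np.finfo(float).tiny) * X
    np.fill_diagonal(Y, 0.0)
    return WeightedGraph(X=X, Y=Y), BlockAssignment(z=z, Q=params.Q)
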