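"""Directed weighted graph container coupling edge existence and weights."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ValidationError

__all__ = ["WeightedGraph"]


@dataclass(frozen=True)
class WeightedGraph:
    """A directed graph with binary adjacency ``X`` and weights ``Y``.

    Off the diagonal, ``Y[i, j] > 0`` exactly when ``X[i, j] == 1`` (a
    missing edge carries weight 0, a present edge a strictly positive
    weight); the diagonal is zero (no self-loops).
    """

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValidationError("X must be a square matrix")
        if Y.shape != X.shape:
            raise ValidationError("Y must have the same shape as X")
        if not np.isin(X, (0.0, 1.0)).all():
            raise ValidationError("X entries must be 0 or 1")
        if np.any(np.diag(X) != 0) or np.any(np.diag(Y) != 0):
            raise ValidationError("self-loops are not allowed (diagonal must be 0)")
        if np.any(Y < 0):
            raise ValidationError("weights must be nonnegative")
        support = Y > 0
        if not np.array_equal(support, X.astype(bool)):
            raise ValidationError(
                "support mismatch: Y must be positive exactly where X == 1"
            )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @classmethod
    def from_weights(cls, Y: np.ndarray) -> "WeightedGraph":
        """Build a graph from a weight matrix; X is inferred from Y > 0."""
        Y = np.asarray(Y, dtype=float)
        return cls(X=(Y > 0).astype(float), Y=Y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.X.sum())

    def density(self) -> float:
        """Fraction of the n(n-1) ordered pairs that carry an edge."""
        n = self.n
        return self.n_edges / (n * (n - 1)) if n > 1 else 0.0

    def edge_weights(self) -> np.ndarray:
        """Weights of existing edges, in row-major edge order."""
        return self.Y[self.X.astype(bool)]

    def log_weights(self) -> np.ndarray:
        """Matrix with log Y on edges and 0 elsewhere (cached)."""
        try:
            return self._logY  # type: ignore[attr-defined]
        except AttributeError:
            pass
        mask = self.X.astype(bool)
        logY = np.zeros_like(self.Y)
        logY[mask] = np.log(self.Y[mask])
        object.__setattr__(self, "_logY", logY)
        return logY
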