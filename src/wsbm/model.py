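"""Model and results objects for variational WSBM fitting.

``WSBM`` holds a graph and a block count; ``WSBM.fit`` runs multi-restart
variational EM and returns a ``WSBMResults`` carrying the estimated
parameters, the variational posterior, the ELBO trace and convergence
metadata, with ``summary()``, ``icl()`` and alignment helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import align_labels
from .graph import WeightedGraph
from .params import BlockAssignment, WSBMParams
from .variational import (
    EmptyBlockError,
    FitConfig,
    VariationalPosterior,
    _coordinate_ascent,
    initial_tau_random,
    initial_tau_spectral,
)

__all__ = ["WSBM", "WSBMResults", "fit_vem", "AllRestartsFailedError"]

logger = logging.getLogger("wsbm")


class AllRestartsFailedError(RuntimeError):
    """Every restart lost a block; the requested Q is likely too large."""


@dataclass
class WSBMResults:
    """Outcome of a variational EM fit.

    Attributes
    ----------
    params : WSBMParams
        Estimated (theta, pi, alpha, beta) of the best restart.
    posterior : VariationalPosterior
        Final membership probabilities tau.
    elbo_trace : list of float
        ELBO at initialization and after each outer iteration of the best
        restart; non-decreasing up to roundoff.
    restart_index, seed, n_iter, converged, degenerate
        Bookkeeping of the winning restart.
    """

    model: "WSBM"
    params: WSBMParams
    posterior: VariationalPosterior
    elbo_trace: list
    n_iter: int
    converged: bool
    degenerate: bool
    restart_index: int
    seed: int | None
    restart_log: list

    @property
    def graph(self) -> WeightedGraph:
        return self.model.graph

    @property
    def Q(self) -> int:
        return self.params.Q

    @property
    def elbo(self) -> float:
        return float(self.elbo_trace[-1])

    @property
    def tau(self) -> np.ndarray:
        return self.posterior.tau

    def labels(self) -> BlockAssignment:
        """Hard assignment: row-wise argmax of tau (lowest index on ties)."""
        return BlockAssignment(z=self.posterior.hard_assignment(), Q=self.Q)

    def icl(self, penalty: str = "printed") -> float:
        from .model_selection import icl

        return icl(self.graph, self, penalty=penalty)

    def align(
        self,
        reference,
        reference_pi: np.ndarray | None = None,
    ) -> np.ndarray:
        """Permutation matching this fit's blocks to a reference.

        See :func:`wsbm.alignment.align_labels`; with a
        :class:`BlockAssignment` reference the fitted ``pi`` and, when
        given, ``reference_pi`` break ties.
        """
        if isinstance(reference, WSBMParams) and reference_pi is None:
            reference_pi = reference.pi
        return align_labels(
            self.labels().z, reference, pi=self.params.pi, reference_pi=reference_pi
        )

    def recovery_errors(
        self, truth: WSBMParams, z_true: BlockAssignment
    ) -> dict:
        """Aligned accuracy and parameter error norms against the truth.

        Alignment minimizes misclassification against ``z_true`` (ties by
        pi distance); errors are the 2-norm for theta and Frobenius norms
        for pi, alpha, beta, all computed after relabeling.
        """
        sigma = align_labels(
            self.labels().z, z_true, pi=self.params.pi, reference_pi=truth.pi
        )
        aligned = self.params.permuted(sigma)
        acc = float(np.mean(sigma[self.labels().z] == z_true.z))
        return {
            "sigma": sigma,
            "accuracy": acc,
            "theta_err": float(np.linalg.norm(aligned.theta - truth.theta)),
            "pi_err": float(np.linalg.norm(aligned.pi - truth.pi)),
            "alpha_err": float(np.linalg.norm(aligned.alpha - truth.alpha)),
            "beta_err": float(np.linalg.norm(aligned.beta - truth.beta)),
        }

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        p = self.params
        lines = [
            "Weighted stochastic block model (variational EM)",
            "=" * 48,
            f"vertices: {self.graph.n}    edges: {self.graph.n_edges}"
            f"    blocks: {self.Q}",
            f"ELBO: {self.elbo:.6f}    iterations: {self.n_iter}"
            f"    converged: {self.converged}",
            f"restart: {self.restart_index}    degenerate: {self.degenerate}",
            "",
            "block proportions (theta):",
            "  " + "  ".join(f"{t:.4f}" for t in p.theta),
            "edge probabilities (pi):",
        ]
        for row in p.pi:
            lines.append("  " + "  ".join(f"{v:.4f}" for v in row))
        lines.append("gamma shape (alpha):")
        for row in p.alpha:
            lines.append("  " + "  ".join(f"{v:.4f}" for v in row))
        lines.append("gamma rate (beta):")
        for row in p.beta:
            lines.append("  " + "  ".join(f"{v:.4f}" for v in row))
        lines.append("gamma mean weight (alpha/beta):")
        for row in p.alpha / p.beta:
            lines.append("  " + "  ".join(f"{v:.4f}" for v in row))
        return "\n".join(lines)

    def plot_elbo(self, ax=None):
        """Diagnostic plot of the ELBO trace (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.elbo_trace, marker=".")
        ax.set_xlabel("outer iteration")
        ax.set_ylabel("ELBO")
        ax.set_title(f"variational EM trace (Q={self.Q})")
        return ax


class WSBM:
    """Weighted stochastic block model bound to one observed graph.

    Parameters
    ----------
    graph : WeightedGraph
        Directed graph with coupled adjacency and weight matrices.
    Q : int
        Number of latent blocks to fit.
    config : FitConfig, optional
        Optimization knobs; defaults are sensible for graphs up to a few
        thousand vertices.
    """

    def __init__(self, graph: WeightedGraph, Q: int, config: FitConfig | None = None):
        if Q < 1:
            raise ValueError("Q must be >= 1")
        self.graph = graph
        self.Q = int(Q)
        self.config = config if config is not None else FitConfig()

    @classmethod
    def from_file(cls, path, Q: int, fmt: str = "edge_list", **kwargs) -> "WSBM":
        from .io import GraphFileSpec, read_graph

        spec = GraphFileSpec(path=path, fmt=fmt, **kwargs)
        return cls(read_graph(spec), Q)

    def fit(self, seed: int | None = None) -> WSBMResults:
        """Run multi-restart variational EM and keep the best restart.

        Restart 0 uses the spectral-style k-means initialization (unless
        ``config.init == 'random'``); the remaining ``restarts - 1`` use
        random membership draws.  Restart r derives its randomness from
        child r of ``seed``.  Restarts that converged with an effectively
        empty block are excluded from the argmax unless all did.
        """
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(cfg.restarts)
        outcomes = []
        for r in range(cfg.restarts):
            child_int = int(children[r].generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(children[r])
            try:
                if r == 0 and cfg.init == "spectral":
                    tau0 = initial_tau_spectral(self.graph, self.Q, seed=child_int)
                else:
                    tau0 = initial_tau_random(rng, self.graph.n, self.Q)
                out = _coordinate_ascent(self.graph, self.Q, tau0, cfg)
            except EmptyBlockError as err:
                logger.info("restart %d failed: %s", r, err)
                outcomes.append(None)
                continue
            out["restart"] = r
            outcomes.append(out)
            logger.info(
                "restart %d: %d iterations, ELBO %.6f, degenerate=%s",
                r,
                out["n_iter"],
                out["elbo"],
                out["degenerate"],
            )

        valid = [o for o in outcomes if o is not None]
        if not valid:
            raise AllRestartsFailedError(
                f"all {cfg.restarts} restarts lost a block; try a smaller Q"
            )
        non_deg = [o for o in valid if not o["degenerate"]]
        pool = non_deg if non_deg else valid
        best = max(pool, key=lambda o: o["elbo"])
        restart_log = [
            {
                "restart": o["restart"],
                "n_iter": o["n_iter"],
                "elbo": o["elbo"],
                "degenerate": o["degenerate"],
            }
            for o in valid
        ]
        return WSBMResults(
            model=self,
            params=best["params"],
            posterior=VariationalPosterior(tau=best["tau"]),
            elbo_trace=best["trace"],
            n_iter=best["n_iter"],
            converged=best["converged"],
            degenerate=best["degenerate"],
            restart_index=best["restart"],
            seed=seed,
            restart_log=restart_log,
        )


def fit_vem(
    graph: WeightedGraph,
    Q: int,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> WSBMResults:
    """Functional entry point: ``WSBM(graph, Q, config).fit(seed)``."""
    return WSBM(graph, Q, config=config).fit(seed=seed)
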