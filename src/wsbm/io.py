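"""Readers and writers for graphs, parameter sets and fit results.

On-disk conventions: vertex ids are 1-based, weights are 64-bit floats,
and a weight of exactly zero means "no edge".  Three graph formats are
supported:

- ``edge_list``: tab-separated with header ``source\\ttarget\\tweight``,
  one line per existing edge (weight > 0);
- ``dense_pair``: two comma-separated dense matrices at ``<path>.X.csv``
  and ``<path>.Y.csv``;
- ``matrix_market``: coordinate-format weights; adjacency inferred from
  the support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .graph import WeightedGraph
from .params import ValidationError, WSBMParams

__all__ = [
    "GraphFileSpec",
    "GraphFormatError",
    "read_graph",
    "write_graph",
    "read_params",
    "write_params",
    "write_fit",
    "read_fit",
]

FORMATS = ("edge_list", "dense_pair", "matrix_market")


class GraphFormatError(ValueError):
    """Malformed graph file; the message carries the offending line."""


@dataclass
class GraphFileSpec:
    """Location and interpretation of a graph file.

    ``undirected=True`` materializes each listed edge in both directions
    with the same weight; fitting still uses the directed model.  ``n``
    overrides the vertex count inferred from the maximum vertex id (needed
    when trailing vertices are isolated).
    """

    path: str | Path
    fmt: str = "edge_list"
    undirected: bool = False
    n: int | None = None

    def __post_init__(self) -> None:
        if self.fmt not in FORMATS:
            raise ValueError(f"fmt must be one of {FORMATS}")
        self.path = Path(self.path)


def _read_edge_list(spec: GraphFileSpec) -> WeightedGraph:
    edges: dict[tuple[int, int], float] = {}
    max_id = 0
    with open(spec.path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t")[:3] != ["source", "target", "weight"]:
        raise GraphFormatError(
            f"{spec.path}:1: expected header 'source\\ttarget\\tweight'"
        )
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GraphFormatError(f"{spec.path}:{ln}: expected 3 tab-separated fields")
        try:
            i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as err:
            raise GraphFormatError(f"{spec.path}:{ln}: {err}") from None
        if i < 1 or j < 1:
            raise GraphFormatError(f"{spec.path}:{ln}: vertex ids are 1-based")
        if i == j:
            raise GraphFormatError(f"{spec.path}:{ln}: self-loop on vertex {i}")
        if not w > 0:
            raise GraphFormatError(
                f"{spec.path}:{ln}: listed edge must have weight > 0 (got {w})"
            )
        key = (i - 1, j - 1)
        if key in edges:
            raise GraphFormatError(f"{spec.path}:{ln}: duplicate edge ({i}, {j})")
        edges[key] = w
        if spec.undirected:
            rkey = (j - 1, i - 1)
            if rkey in edges:
                raise GraphFormatError(
                    f"{spec.path}:{ln}: edge ({j}, {i}) already listed "
                    "(undirected input lists each pair once)"
                )
            edges[rkey] = w
        max_id = max(max_id, i, j)
    n = spec.n if spec.n is not None else max_id
    if n < max_id:
        raise GraphFormatError(f"{spec.path}: n={n} smaller than max vertex id {max_id}")
    Y = np.zeros((n, n))
    for (i, j), w in edges.items():
        Y[i, j] = w
    return WeightedGraph.from_weights(Y)


def read_graph(spec: GraphFileSpec) -> WeightedGraph:
    """Read a graph file into a validated :class:`WeightedGraph`."""
    if spec.fmt == "edge_list":
        return _read_edge_list(spec)
    if spec.fmt == "dense_pair":
        X = np.loadtxt(f"{spec.path}.X.csv", delimiter=",", ndmin=2)
        Y = np.loadtxt(f"{spec.path}.Y.csv", delimiter=",", ndmin=2)
        if spec.undirected:
            X, Y = np.maximum(X, X.T), np.maximum(Y, Y.T)
        try:
            return WeightedGraph(X=X, Y=Y)
        except ValidationError as err:
            raise GraphFormatError(f"{spec.path}: {err}") from None
    # matrix market
    Y = np.asarray(scipy.io.mmread(spec.path).todense(), dtype=float)
    if spec.undirected:
        Y = np.maximum(Y, Y.T)
    if spec.n is not None and spec.n > Y.shape[0]:
        pad = spec.n - Y.shape[0]
        Y = np.pad(Y, ((0, pad), (0, pad)))
    try:
        return WeightedGraph.from_weights(Y)
    except ValidationError as err:
        raise GraphFormatError(f"{spec.path}: {err}") from None


def write_graph(graph: WeightedGraph, spec: GraphFileSpec) -> None:
    """Write a graph in the requested format (directed as stored)."""
    if spec.fmt == "edge_list":
        with open(spec.path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for i, j in np.argwhere(graph.X == 1.0):
                fh.write(f"{i + 1}\t{j + 1}\t{graph.Y[i, j]:.17g}\n")
    elif spec.fmt == "dense_pair":
        np.savetxt(f"{spec.path}.X.csv", graph.X, delimiter=",", fmt="%.17g")
        np.savetxt(f"{spec.path}.Y.csv", graph.Y, delimiter=",", fmt="%.17g")
    else:
        scipy.io.mmwrite(
            str(spec.path), scipy.sparse.coo_matrix(graph.Y), precision=17
        )


def read_params(path) -> WSBMParams:
    """Read a parameter set from a JSON document."""
    with open(path) as fh:
        return WSBMParams.from_dict(json.load(fh))


def write_params(params: WSBMParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
        fh.write("\n")


def write_fit(fit, path, extra: dict | None = None) -> None:
    """Serialize a fit result (parameters, tau, trace, seed) as JSON."""
    from . import __version__

    cfg = fit.model.config if fit.model is not None else None
    doc = {
        "version": __version__,
        "seed": fit.seed,
        "Q": fit.Q,
        "params": fit.params.to_dict(),
        "tau": fit.tau.tolist(),
        "elbo_trace": list(map(float, fit.elbo_trace)),
        "n_iter": fit.n_iter,
        "converged": bool(fit.converged),
        "degenerate": bool(fit.degenerate),
        "restart_index": fit.restart_index,
        "restart_log": fit.restart_log,
        "config": None
        if cfg is None
        else {
            "restarts": cfg.restarts,
            "max_iter": cfg.max_iter,
            "tol": cfg.tol,
            "damping": cfg.damping,
            "max_inner": cfg.max_inner,
            "inner_tol": cfg.inner_tol,
            "init": cfg.init,
            "box": {
                "alpha_c": cfg.box.alpha_c,
                "alpha_C": cfg.box.alpha_C,
                "beta_c": cfg.box.beta_c,
                "beta_C": cfg.box.beta_C,
                "zeta": cfg.box.zeta,
                "gamma_min": cfg.box.gamma_min,
            },
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_fit(path, graph: WeightedGraph | None = None):
    """Read a fit document back into a :class:`~wsbm.model.WSBMResults`.

    Supplying the graph restores the full results object (needed e.g. to
    recompute ICL); without it the graph-dependent methods are unusable.
    """
    from .model import WSBM, WSBMResults
    from .variational import VariationalPosterior

    with open(path) as fh:
        doc = json.load(fh)
    params = WSBMParams.from_dict(doc["params"])
    model = WSBM(graph, params.Q) if graph is not None else None
    return WSBMResults(
        model=model,
        params=params,
        posterior=VariationalPosterior(tau=np.asarray(doc["tau"])),
        elbo_trace=doc["elbo_trace"],
        n_iter=doc["n_iter"],
        converged=doc["converged"],
        degenerate=doc["degenerate"],
        restart_index=doc["restart_index"],
        seed=doc["seed"],
        restart_log=doc.get("restart_log", []),
    )
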