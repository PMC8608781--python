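"""Choosing the number of blocks with the approximate ICL criterion.

ICL evaluates the complete-data log-likelihood at the hard assignment
(argmax of tau) plus the mixing log-probability of those labels, penalized
by a BIC-style term: ``-(3/2) Q(Q+1) log(n(n-1)) - ((Q-1)/2) log n``.
The fitted parameters are plugged in as the maximizer (fit-then-evaluate,
as in the Daudin-style ICL for binary SBMs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import WeightedGraph
from .likelihood import complete_loglik
from .model import AllRestartsFailedError, WSBM, WSBMResults
from .variational import FitConfig

__all__ = ["icl", "icl_penalty", "select_q", "ICLResult"]


def icl_penalty(Q: int, n: int, penalty: str = "printed") -> float:
    """Model-complexity penalty of the approximate ICL.

    ``printed`` is the default form ``-(3/2) Q(Q+1) log(n(n-1)) -
    ((Q-1)/2) log n``; ``directed`` substitutes the 3Q^2 block-pair
    parameter count of a fully directed model for Q(Q+1).
    """
    if penalty == "printed":
        pair_terms = Q * (Q + 1)
    elif penalty == "directed":
        pair_terms = 2 * Q * Q
    else:
        raise ValueError("penalty must be 'printed' or 'directed'")
    return -1.5 * pair_terms * np.log(n * (n - 1)) - 0.5 * (Q - 1) * np.log(n)


def icl(graph: WeightedGraph, fit: WSBMResults, penalty: str = "printed") -> float:
    """Approximate ICL of a fitted model on its graph."""
    zhat = fit.labels()
    with np.errstate(divide="ignore"):
        log_theta = np.log(fit.params.theta)
    completed = complete_loglik(graph, zhat, fit.params) + float(
        log_theta[zhat.z].sum()
    )
    return completed + icl_penalty(fit.Q, graph.n, penalty=penalty)


@dataclass
class ICLResult:
    """Per-Q ICL records from a sweep and the selected block count."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)

    @property
    def selected_Q(self) -> int:
        ok = self.table.dropna(subset=["icl"])
        best = ok["icl"].max()
        # parsimony: smallest Q within exact argmax ties
        return int(ok.loc[ok["icl"] == best, "Q"].min())


def select_q(
    graph: WeightedGraph,
    Q_range,
    config: FitConfig | None = None,
    seed: int | None = None,
    penalty: str = "printed",
    keep_fits: bool = False,
) -> ICLResult:
    """Fit every Q in ``Q_range`` and rank them by ICL.

    Each Q gets fresh restarts with its own child seed.  A Q whose every
    restart collapses is recorded as missing rather than aborting the
    sweep.
    """
    Q_range = list(Q_range)
    if not Q_range:
        raise ValueError("Q_range must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(Q_range))
    rows = []
    fits = {}
    for child, Q in zip(children, Q_range):
        q_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            fit = WSBM(graph, Q, config=config).fit(seed=q_seed)
        except AllRestartsFailedError:
            rows.append(
                {"Q": Q, "completed_loglik": np.nan, "penalty": np.nan, "icl": np.nan}
            )
            continue
        pen = icl_penalty(Q, graph.n, penalty=penalty)
        val = icl(graph, fit, penalty=penalty)
        rows.append(
            {"Q": Q, "completed_loglik": val - pen, "penalty": pen, "icl": val}
        )
        if keep_fits:
            fits[Q] = fit
    table = pd.DataFrame(rows)
    if table["icl"].isna().all():
        raise AllRestartsFailedError("no Q in the sweep produced a usable fit")
    return ICLResult(table=table, fits=fits)
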