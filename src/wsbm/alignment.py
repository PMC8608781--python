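"""Label-switching alignment.

Block models are invariant under a simultaneous permutation of labels and
parameter rows/columns, so error metrics are only meaningful after
aligning the fitted blocks with a reference.  The search is exhaustive
over the Q! permutations (capped), matching the convention that
``sigma[q]`` is the reference block corresponding to fitted block ``q``.
"""

from __future__ import annotations

import itertools

import numpy as np

from .params import BlockAssignment, WSBMParams

__all__ = ["align_labels", "permute_matrix", "permutation_for_params"]

_MAX_Q = 8  # 8! = 40320 permutations


def permute_matrix(M: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Relabel a Q x Q block matrix: out[sigma[q], sigma[l]] = M[q, l]."""
    sigma = np.asarray(sigma)
    inv = np.argsort(sigma)
    return M[np.ix_(inv, inv)]


def align_labels(
    labels: np.ndarray,
    reference,
    pi: np.ndarray | None = None,
    reference_pi: np.ndarray | None = None,
) -> np.ndarray:
    """Permutation mapping fitted block indices onto a reference.

    Parameters
    ----------
    labels : (n,) int array
        Hard (argmax-tau) labels from a fit.
    reference : BlockAssignment or WSBMParams
        With a label reference, the permutation minimizing the
        misclassification count of ``sigma[labels]`` is returned, ties
        broken by the Frobenius distance of the permuted ``pi`` to the
        reference ``pi`` when available.  With a parameter reference, the
        permutation minimizing the summed squared parameter distance is
        returned.
    pi : optional (Q, Q) array
        Fitted edge-probability matrix, used for tie-breaking / parameter
        alignment.

    Returns
    -------
    sigma : (Q,) int array with ``sigma[q]`` the reference block for
        fitted block ``q``.
    """
    if isinstance(reference, BlockAssignment):
        Q = reference.Q
        if Q > _MAX_Q:
            raise ValueError(f"exhaustive alignment supports Q <= {_MAX_Q}")
        labels = np.asarray(labels)
        best = None
        for perm in itertools.permutations(range(Q)):
            sigma = np.asarray(perm)
            errs = int(np.sum(sigma[labels] != reference.z))
            key = (errs,)
            if pi is not None and reference_pi is not None:
                key = (
                    errs,
                    float(np.linalg.norm(permute_matrix(pi, sigma) - reference_pi)),
                )
            if best is None or key < best[0]:
                best = (key, sigma)
        return best[1]
    if isinstance(reference, WSBMParams):
        return permutation_for_params(reference, pi=pi, labels=labels)
    raise TypeError("reference must be a BlockAssignment or WSBMParams")


def permutation_for_params(
    reference: WSBMParams,
    fitted: WSBMParams | None = None,
    pi: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Permutation minimizing squared parameter distance to a reference."""
    Q = reference.Q
    if Q > _MAX_Q:
        raise ValueError(f"exhaustive alignment supports Q <= {_MAX_Q}")
    best = None
    for perm in itertools.permutations(range(Q)):
        sigma = np.asarray(perm)
        d = 0.0
        if fitted is not None:
            d += float(np.sum((fitted.theta[np.argsort(sigma)] - reference.theta) ** 2))
            for M, R in (
                (fitted.pi, reference.pi),
                (fitted.alpha, reference.alpha),
                (fitted.beta, reference.beta),
            ):
                d += float(np.sum((permute_matrix(M, sigma) - R) ** 2))
        elif pi is not None:
            d = float(np.sum((permute_matrix(pi, sigma) - reference.pi) ** 2))
        else:
            raise ValueError("need fitted params or pi to align against parameters")
        if best is None or d < best[0]:
            best = (d, sigma)
    return best[1]
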