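"""Weighted Markov clustering for orthologue-network components.

Standard MCL: column-normalize the weighted adjacency (with self-loops),
then alternate expansion (matrix squaring) with inflation (entry-wise power
followed by renormalization) until the matrix stops changing.  Clusters are
read off the attractors of the limit matrix.  Components here are small
(rarely more than a few dozen nodes), so a dense matrix is used throughout.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["mcl_partition"]


def mcl_partition(
    weights: np.ndarray,
    inflation: float = 1.2,
    pruning: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[set[int]]:
    """Partition node indices 0..n-1 of a symmetric weight matrix.

    Self-loops are set to each node's maximum incident weight before
    normalization.  On non-convergence the current interpretation is
    returned with a warning.  Nodes attracted by no attractor attach to
    the cluster containing their strongest neighbour.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    if n == 0:
        return []
    if n == 1:
        return [{0}]
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    M = W.copy()
    np.fill_diagonal(M, 0.0)
    diag = M.max(axis=0)
    diag[diag == 0.0] = 1.0  # isolated nodes get a unit self-loop
    np.fill_diagonal(M, diag)
    M = _normalize(M)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < pruning] = 0.0
        M = _normalize(M)
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)
    return _interpret(M, W)


def _normalize(M: np.ndarray) -> np.ndarray:
    col = M.sum(axis=0)
    col[col == 0.0] = 1.0
    return M / col


def _interpret(M: np.ndarray, W: np.ndarray) -> list[set[int]]:
    n = M.shape[0]
    attractors = [i for i in range(n) if M[i, i] > 0.0]
    clusters: list[set[int]] = []
    for i in attractors:
        members = set(np.nonzero(M[i] > 0.0)[0]) | {i}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if merged:
            # merging may chain-connect earlier clusters
            clusters = _coalesce(clusters)
        else:
            clusters.append(members)
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            nbr = np.argsort(-W[i])
            target = None
            for j in nbr:
                if W[i, j] > 0 and j in assigned:
                    target = j
                    break
            if target is None:
                clusters.append({i})
            else:
                for c in clusters:
                    if target in c:
                        c.add(i)
                        break
            assigned.add(i)
    return _coalesce(clusters)


def _coalesce(clusters: list[set[int]]) -> list[set[int]]:
    out: list[set[int]] = []
    for c in clusters:
        c = set(c)
        keep = []
        for o in out:
            if o & c:
                c |= o
            else:
                keep.append(o)
        keep.append(c)
        out = keep
    return out
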