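"""Google matrix construction, PageRank, CheiRank, 2DRank and creative-element scores.

The Google matrix of a directed network of ``N`` nodes is

    G = alpha * S + (1 - alpha) / N,

where ``S`` is the column-stochastic transition matrix built from the 0/1
adjacency ``A`` (``A[i, j] = 1`` iff node j points to node i):
``S[:, j] = A[:, j] / k_out(j)`` for nodes with outgoing links, and a uniform
column ``1/N`` for dangling nodes (``k_out = 0``).  The damping factor
``alpha`` is the probability of following a link rather than teleporting to a
uniformly random node; 0.85 throughout, as is conventional.

``G`` is never stored densely.  :class:`GoogleModel` keeps the sparse link
part plus the dangling mask and applies ``G`` to vectors matrix-free, which
is all that power iteration (PageRank) and Arnoldi (spectrum) need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import DirectedNetwork

__all__ = [
    "DEFAULT_ALPHA",
    "GoogleModel",
    "RankResult",
    "build_transition",
    "pagerank",
    "cheirank",
    "two_d_rank",
    "creative_scores",
    "rank_indexes",
]

DEFAULT_ALPHA = 0.85


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested residual."""


@dataclass
class GoogleModel:
    """Matrix-free representation of S and G for one network.

    ``sparse_S`` holds only the link-following part: columns ``A[:, j]/k_out(j)``
    for non-dangling j and all-zero columns for dangling j.  The uniform
    ``1/N`` columns of dangling nodes and the ``(1-alpha)/N`` teleportation
    term are applied analytically, so ``G`` costs one sparse mat-vec plus two
    rank-one corrections per application.
    """

    sparse_S: sp.csr_matrix
    dangling_mask: np.ndarray
    alpha: float
    node_labels: list[str]

    @property
    def N(self) -> int:
        return self.sparse_S.shape[0]

    def apply_S(self, v: np.ndarray) -> np.ndarray:
        """S @ v including the uniform dangling columns."""
        v = np.asarray(v)
        if v.shape[0] != self.N:
            raise ValueError(f"vector length {v.shape[0]} != N = {self.N}")
        dangling_sum = v[self.dangling_mask].sum(axis=0)
        return self.sparse_S @ v + dangling_sum / self.N

    def apply_G(self, v: np.ndarray) -> np.ndarray:
        """G @ v = alpha * S @ v + (1 - alpha) * sum(v) / N.

        Preserves the sum of ``v``: columns of G sum to one.
        """
        v = np.asarray(v)
        return self.alpha * self.apply_S(v) + (1.0 - self.alpha) * v.sum(axis=0) / self.N

    def apply_G_transpose(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v)
        if v.shape[0] != self.N:
            raise ValueError(f"vector length {v.shape[0]} != N = {self.N}")
        out = self.alpha * (self.sparse_S.T @ v)
        out[self.dangling_mask] += self.alpha * v.sum() / self.N
        return out + (1.0 - self.alpha) * v.sum() / self.N

    def dense_S(self) -> np.ndarray:
        """Dense S for small test instances; production code stays matrix-free."""
        S = self.sparse_S.toarray()
        S[:, self.dangling_mask] = 1.0 / self.N
        return S

    def dense_G(self) -> np.ndarray:
        return self.alpha * self.dense_S() + (1.0 - self.alpha) / self.N


@dataclass
class RankResult:
    """PageRank-style probabilities and their rank indexes.

    ``P`` sums to one; ``K`` is a permutation of 1..N with ``K = 1`` for the
    most probable node.  ``P_star``/``K_star`` (CheiRank) and ``K2`` (2DRank)
    are filled by the higher-level drivers when both directions are computed.
    """

    node_labels: list[str]
    P: np.ndarray
    K: np.ndarray
    P_star: np.ndarray | None = None
    K_star: np.ndarray | None = None
    K2: np.ndarray | None = None
    n_iter: int = 0
    residual: float = field(default=0.0)

    def rank_of(self, label: str) -> int:
        return int(self.K[self.node_labels.index(label)])


def build_transition(net: DirectedNetwork, alpha: float = DEFAULT_ALPHA) -> GoogleModel:
    """Build the matrix-free Google model for a network.

    Column j of S is ``A[:, j] / k_out(j)`` when node j has outgoing links
    and uniform ``1/N`` when it is dangling.
    """
    if net.N == 0:
        raise ValueError("cannot build a transition matrix for an empty network")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    A = net.adjacency().tocsc()
    k_out = np.asarray(A.sum(axis=0)).ravel()
    dangling = k_out == 0
    scale = np.ones_like(k_out)
    scale[~dangling] = k_out[~dangling]
    S = (A @ sp.diags(1.0 / scale)).tocsr()
    return GoogleModel(S, dangling, alpha, list(net.node_labels))


def rank_indexes(P: np.ndarray, node_labels: list[str]) -> np.ndarray:
    """Descending-probability rank index, ties broken by ascending label.

    Returns ``K`` with ``K[i]`` the 1-based rank of node ``i``.
    """
    order = sorted(range(len(P)), key=lambda i: (-P[i], node_labels[i]))
    K = np.empty(len(P), dtype=np.int64)
    K[order] = np.arange(1, len(P) + 1)
    return K


def pagerank(
    model: GoogleModel,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    start: np.ndarray | None = None,
) -> RankResult:
    """PageRank by power iteration on the matrix-free G.

    Iterates ``P <- G P`` from a uniform start until the L1 residual
    ``||G P - P||_1`` drops below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    N = model.N
    v = np.full(N, 1.0 / N) if start is None else np.asarray(start, dtype=float) / np.sum(start)
    residual = np.inf
    for it in range(1, max_iter + 1):
        w = model.apply_G(v)
        w /= w.sum()  # guard against drift; G preserves the sum analytically
        residual = float(np.abs(w - v).sum())
        v = w
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {max_iter} iterations (residual {residual:.3e})"
        )
    K = rank_indexes(v, model.node_labels)
    return RankResult(model.node_labels, v, K, n_iter=it, residual=residual)


def cheirank(
    net: DirectedNetwork,
    alpha: float = DEFAULT_ALPHA,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> RankResult:
    """CheiRank: the PageRank of the link-reversed network.

    Dangling handling is applied to the reversed network independently —
    a node with no *incoming* links in the original network becomes a
    dangling node of ``G*``.
    """
    return pagerank(build_transition(net.reversed(), alpha), tol=tol, max_iter=max_iter)


def two_d_rank(K: np.ndarray, K_star: np.ndarray) -> np.ndarray:
    """Combined 2DRank index from PageRank and CheiRank indexes.

    Nodes are visited by sweeping squares of growing size ``s`` anchored at
    ``K = K* = 1`` in the (K, K*) plane: at size ``s`` the newly covered
    cells are the right column (``K = s``, scanned top-to-bottom, i.e. by
    increasing K*) followed by the new bottom row (``K* = s``, scanned
    left-to-right by increasing K).  ``K2[i]`` is the 1-based position of
    node ``i`` in this sweep.
    """
    K = np.asarray(K)
    K_star = np.asarray(K_star)
    N = len(K)
    for arr, name in ((K, "K"), (K_star, "K_star")):
        if sorted(arr) != list(range(1, N + 1)):
            raise ValueError(f"{name} is not a permutation of 1..{N}")
    by_cell = {(int(K[i]), int(K_star[i])): i for i in range(N)}
    K2 = np.empty(N, dtype=np.int64)
    pos = 1
    for s in range(1, N + 1):
        for ks in range(1, s + 1):  # new right column, top to bottom
            i = by_cell.get((s, ks))
            if i is not None:
                K2[i] = pos
                pos += 1
        for k in range(1, s):  # new bottom row, left to right
            i = by_cell.get((k, s))
            if i is not None:
                K2[i] = pos
                pos += 1
    return K2


def creative_scores(
    K: np.ndarray,
    K_star: np.ndarray,
    in_degree: np.ndarray,
    out_degree: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Creative-element scores CE_in = K * (InDegree + 1), CE_out = K* * (OutDegree + 1).

    Large scores flag nodes whose centrality is *not* explained by raw
    connectivity — candidate "creative elements" that acquire importance
    through the network structure beyond their degree.
    """
    in_degree = np.asarray(in_degree)
    out_degree = np.asarray(out_degree)
    if (in_degree < 0).any() or (out_degree < 0).any():
        raise ValueError("degrees must be non-negative")
    ce_in = np.asarray(K) * (in_degree + 1)
    ce_out = np.asarray(K_star) * (out_degree + 1)
    return ce_in, ce_out


def full_ranking(
    net: DirectedNetwork,
    alpha: float = DEFAULT_ALPHA,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> RankResult:
    """PageRank + CheiRank + 2DRank in one RankResult for a network."""
    model = build_transition(net, alpha)
    res = pagerank(model, tol=tol, max_iter=max_iter)
    chei = cheirank(net, alpha, tol=tol, max_iter=max_iter)
    res.P_star = chei.P
    res.K_star = chei.K
    res.K2 = two_d_rank(res.K, res.K_star)
    return res
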