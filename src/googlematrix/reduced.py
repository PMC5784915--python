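"""Reduced Google matrix of a node subset and its three-component decomposition.

Given the Google matrix ``G`` of a large directed network and a subset of
``N_r`` nodes of interest (a pathway, a gene signature), write ``G`` in
block form with respect to the subset ("reduced", index r) and its
complement ("scattering network", index s)::

    G = [[G_rr, G_rs],
         [G_sr, G_ss]]

The reduced Google matrix

    G_R = G_rr + G_rs (1 - G_ss)^{-1} G_sr

is an ``N_r x N_r`` column-stochastic matrix whose fixed point is the
restriction of the global PageRank to the subset (up to normalization):
direct transitions within the subset plus *every* indirect path through the
rest of the network, resummed to all orders via the resolvent
``(1 - G_ss)^{-1} = sum_l G_ss^l``.

Expanding the resolvent around the leading eigentriple ``(lambda_c, psi_R,
psi_L)`` of ``G_ss`` splits ``G_R`` into three parts::

    G_R  = G_rr + G_pr + G_qr
    G_pr = G_rs P_c G_sr / (1 - lambda_c),   P_c = psi_R psi_L^T
    G_qr = G_rs [ Q_c sum_l (Q_c G_ss Q_c)^l ] G_sr,   Q_c = 1 - P_c

``G_rr`` carries the direct links, ``G_pr`` is an essentially trivial
rank-one background set by the global PageRank, and ``G_qr`` carries the
interesting signal: indirect (hidden) transitions between subset nodes
through the scattering network.  Its diagonal ``G_qrd`` is the probability
of leaving a node and returning to it; the off-diagonal part ``G_qrnd``
scores hidden directed interactions between distinct subset members.

Because the leading eigendirection is deflated by ``Q_c``, the projected
series converges geometrically with ratio roughly ``alpha`` (typically a
few hundred terms), while the rank-one pole at ``lambda_c`` is treated
analytically.  Individual ``G_qr`` entries can come out slightly negative
(``Q_c`` is not positivity-preserving); they are kept verbatim and their
total weight is reported, never clipped.

The dense-resolvent route :func:`reduced_dense` computes ``G_R`` by an
explicit linear solve and serves as an independent cross-check of the
projected-series algorithm on any instance small enough to densify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .google import GoogleModel

__all__ = [
    "BlockPartition",
    "ReducedGoogleMatrix",
    "partition",
    "scattering_eigenpair",
    "compute_reduced",
    "reduced_dense",
    "save_reduced",
]


class SeriesDivergenceError(RuntimeError):
    """The deflated Neumann series failed to converge within max_terms."""


@dataclass
class BlockPartition:
    """Matrix-free block operators of G for a subset/complement split.

    ``S_xy`` are slices of the sparse link part of S (dangling columns
    all-zero); the uniform dangling columns and the teleportation term are
    restored analytically in each block application, so every block is an
    exact slice of the full G.
    """

    subset_indexes: np.ndarray
    complement_indexes: np.ndarray
    S_rr: sp.csr_matrix
    S_rs: sp.csr_matrix
    S_sr: sp.csr_matrix
    S_ss: sp.csr_matrix
    dang_r: np.ndarray  # dangling flags of subset nodes (source role)
    dang_s: np.ndarray  # dangling flags of complement nodes
    alpha: float
    N: int

    @property
    def N_r(self) -> int:
        return len(self.subset_indexes)

    @property
    def N_s(self) -> int:
        return len(self.complement_indexes)

    def _apply(self, S_block, dang_cols: np.ndarray, n_rows: int, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        dangling_sum = v[dang_cols].sum()
        uniform = self.alpha * dangling_sum / self.N + (1.0 - self.alpha) * v.sum() / self.N
        return self.alpha * (S_block @ v) + uniform

    def apply_rr(self, v): return self._apply(self.S_rr, self.dang_r, self.N_r, v)
    def apply_rs(self, v): return self._apply(self.S_rs, self.dang_s, self.N_r, v)
    def apply_sr(self, v): return self._apply(self.S_sr, self.dang_r, self.N_s, v)
    def apply_ss(self, v): return self._apply(self.S_ss, self.dang_s, self.N_s, v)

    def _apply_T(self, S_block, dang_cols: np.ndarray, n_cols: int, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        out = self.alpha * (S_block.T @ w)
        out[dang_cols] += self.alpha * w.sum() / self.N
        return out + (1.0 - self.alpha) * w.sum() / self.N

    def apply_ss_T(self, w): return self._apply_T(self.S_ss, self.dang_s, self.N_s, w)
    def apply_sr_T(self, w): return self._apply_T(self.S_sr, self.dang_r, self.N_r, w)

    def dense_block(self, which: str) -> np.ndarray:
        """Dense slice of G for a block; intended for small instances."""
        S_block, dang = {
            "rr": (self.S_rr, self.dang_r),
            "rs": (self.S_rs, self.dang_s),
            "sr": (self.S_sr, self.dang_r),
            "ss": (self.S_ss, self.dang_s),
        }[which]
        B = self.alpha * S_block.toarray()
        B[:, dang] += self.alpha / self.N
        return B + (1.0 - self.alpha) / self.N


@dataclass
class ReducedGoogleMatrix:
    """Dense N_r x N_r decomposition G_R = G_rr + G_pr + G_qr with diagnostics."""

    subset_labels: list[str]
    G_rr: np.ndarray
    G_pr: np.ndarray
    G_qr: np.ndarray
    lambda_c: float
    one_minus_lambda_c: float
    psi_R: np.ndarray | None
    psi_L: np.ndarray | None
    W_rr: float
    W_pr: float
    W_qr: float
    negative_weight: float
    n_series_terms: int
    alpha: float
    N: int

    @property
    def N_r(self) -> int:
        return len(self.subset_labels)

    @property
    def G_R(self) -> np.ndarray:
        return self.G_rr + self.G_pr + self.G_qr

    @property
    def G_qrd(self) -> np.ndarray:
        """Diagonal part of G_qr: probability to leave a node and return to it."""
        return np.diag(np.diag(self.G_qr))

    @property
    def G_qrnd(self) -> np.ndarray:
        """Off-diagonal part of G_qr: hidden links between distinct subset nodes."""
        return self.G_qr - self.G_qrd


def partition(model: GoogleModel, subset: list[str]) -> BlockPartition:
    """Split the Google model into subset ("reduced") and complement ("scattering") blocks."""
    if not subset:
        raise ValueError("subset must be non-empty")
    label_index = {lab: i for i, lab in enumerate(model.node_labels)}
    missing = [lab for lab in subset if lab not in label_index]
    if missing:
        raise KeyError(f"subset labels not in network: {missing}")
    if len(set(subset)) != len(subset):
        raise ValueError("subset contains duplicate labels")
    r_idx = np.array([label_index[lab] for lab in subset], dtype=np.int64)
    mask = np.ones(model.N, dtype=bool)
    mask[r_idx] = False
    s_idx = np.nonzero(mask)[0]
    S = model.sparse_S.tocsr()
    return BlockPartition(
        subset_indexes=r_idx,
        complement_indexes=s_idx,
        S_rr=S[r_idx][:, r_idx].tocsr(),
        S_rs=S[r_idx][:, s_idx].tocsr(),
        S_sr=S[s_idx][:, r_idx].tocsr(),
        S_ss=S[s_idx][:, s_idx].tocsr(),
        dang_r=model.dangling_mask[r_idx],
        dang_s=model.dangling_mask[s_idx],
        alpha=model.alpha,
        N=model.N,
    )


def scattering_eigenpair(
    part: BlockPartition,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Leading eigentriple (lambda_c, psi_R, psi_L) of the scattering block G_ss.

    Both eigenvectors are found by power iteration (G_ss is a non-negative
    substochastic matrix, so its leading eigenvalue is real with positive
    eigenvectors).  Normalizations: ``sum(psi_R) = 1`` and
    ``psi_L . psi_R = 1``.  ``1 - lambda_c`` is additionally evaluated as
    ``||G_rs psi_R||_1`` — an identity that follows from the column sums of
    G being one — which is accurate even when lambda_c is close to one; the
    two estimates are required to agree.
    """
    if part.N_s < 1:
        raise ValueError("scattering network is empty (N_r = N); decomposition is trivial")
    N_s = part.N_s
    lam = 0.0

    psi = np.full(N_s, 1.0 / N_s)
    for _ in range(max_iter):
        w = part.apply_ss(psi)
        lam = w.sum()  # w >= 0 and sum(psi) = 1, so this is the Rayleigh quotient
        w /= lam
        if np.abs(w - psi).sum() < tol:
            psi = w
            break
        psi = w
    else:
        raise RuntimeError(f"psi_R power iteration did not converge in {max_iter} iterations")

    phi = np.full(N_s, 1.0 / N_s)
    for _ in range(max_iter):
        w = part.apply_ss_T(phi)
        w /= w.sum()
        if np.abs(w - phi).sum() < tol:
            phi = w
            break
        phi = w
    else:
        raise RuntimeError(f"psi_L power iteration did not converge in {max_iter} iterations")

    psi_L = phi / (phi @ psi)

    # re-evaluate lambda on the converged vector: with sum(psi) = 1 the column
    # sums of G give 1 = lambda_c + ||G_rs psi||_1 to machine precision
    lam = float(part.apply_ss(psi).sum())
    one_minus = np.abs(part.apply_rs(psi)).sum()
    if lam >= 1.0:
        raise RuntimeError(f"leading G_ss eigenvalue {lam} >= 1: internal inconsistency")
    if abs((1.0 - lam) - one_minus) > max(10 * tol, 1e-10):
        raise RuntimeError(
            f"eigenvalue estimates disagree: 1-lambda_c = {1 - lam:.3e} "
            f"vs ||G_rs psi_R||_1 = {one_minus:.3e}"
        )
    return lam, psi, psi_L


def _dense_G_sr(part: BlockPartition) -> np.ndarray:
    return part.dense_block("sr")


def compute_reduced(
    model: GoogleModel,
    subset: list[str],
    tol: float = 1e-12,
    max_terms: int = 10_000,
) -> ReducedGoogleMatrix:
    """Compute G_R = G_rr + G_pr + G_qr for a subset by the projected series.

    Algorithm: find the leading eigentriple of G_ss by power iteration;
    form G_pr analytically as the rank-one outer product
    ``(G_rs psi_R)(psi_L^T G_sr) / (1 - lambda_c)``; then, for each subset
    column ``b`` of G_sr, deflate (``b <- Q_c b``) and accumulate the series
    ``sum_l (Q_c G_ss)^l b`` until its L1 increment drops below ``tol``,
    finally mapping back through G_rs to obtain one column of G_qr.

    The degenerate case ``subset == all nodes`` returns G_R = G (dense) with
    zero projector and hidden parts — there is no scattering network.
    """
    if len(subset) == model.N and set(subset) == set(model.node_labels):
        Gfull = model.dense_G()
        perm = [model.node_labels.index(lab) for lab in subset]
        Gfull = Gfull[np.ix_(perm, perm)]
        zeros = np.zeros_like(Gfull)
        return ReducedGoogleMatrix(
            subset_labels=list(subset), G_rr=Gfull, G_pr=zeros, G_qr=zeros.copy(),
            lambda_c=float("nan"), one_minus_lambda_c=float("nan"),
            psi_R=None, psi_L=None,
            W_rr=float(Gfull.sum() / len(subset)), W_pr=0.0, W_qr=0.0,
            negative_weight=0.0, n_series_terms=0, alpha=model.alpha, N=model.N,
        )

    part = partition(model, subset)
    N_r, N = part.N_r, part.N

    lam, psi_R, psi_L = scattering_eigenpair(part, tol=tol)
    one_minus = np.abs(part.apply_rs(psi_R)).sum()

    # direct part: dense slice of G on the subset
    G_rr = part.dense_block("rr")

    # projector part: rank-one outer product of two N_r vectors
    psi_tilde_R = part.apply_rs(psi_R)
    psi_tilde_L = part.apply_sr_T(psi_L)
    G_pr = np.outer(psi_tilde_R, psi_tilde_L) / one_minus

    # hidden part: deflated Neumann series, one subset column at a time
    B = _dense_G_sr(part)  # N_s x N_r, columns are G_sr e_j
    G_qr = np.empty((N_r, N_r))
    max_terms_used = 0

    def Q_c(v: np.ndarray) -> np.ndarray:
        return v - psi_R * (psi_L @ v)

    for j in range(N_r):
        t = Q_c(B[:, j])
        acc = t.copy()
        converged = False
        for l in range(1, max_terms + 1):
            t = Q_c(part.apply_ss(t))
            acc += t
            inc = np.abs(t).sum()
            if inc < tol:
                converged = True
                max_terms_used = max(max_terms_used, l)
                break
        if not converged:
            raise SeriesDivergenceError(
                f"deflated series for column {j} not converged after {max_terms} terms "
                f"(last increment {inc:.3e})"
            )
        G_qr[:, j] = part.apply_rs(acc)

    W_rr = float(G_rr.sum() / N_r)
    W_pr = float(G_pr.sum() / N_r)
    W_qr = float(G_qr.sum() / N_r)
    negative_weight = float(-G_qr[G_qr < 0].sum() / N_r)

    return ReducedGoogleMatrix(
        subset_labels=list(subset),
        G_rr=G_rr, G_pr=G_pr, G_qr=G_qr,
        lambda_c=float(lam), one_minus_lambda_c=float(one_minus),
        psi_R=psi_R, psi_L=psi_L,
        W_rr=W_rr, W_pr=W_pr, W_qr=W_qr,
        negative_weight=negative_weight,
        n_series_terms=max_terms_used,
        alpha=model.alpha, N=N,
    )


def reduced_dense(model: GoogleModel, subset: list[str]) -> np.ndarray:
    """G_R by the explicit dense resolvent: G_rr + G_rs (1 - G_ss)^{-1} G_sr.

    Independent of the projected-series route; feasible for N up to a couple
    of thousand nodes.  Columns of the result sum to one.
    """
    if model.N > 2000:
        raise ValueError("dense resolvent route limited to N <= 2000")
    if len(subset) == model.N:
        G = model.dense_G()
        perm = [model.node_labels.index(lab) for lab in subset]
        return G[np.ix_(perm, perm)]
    part = partition(model, subset)
    G_rr = part.dense_block("rr")
    G_rs = part.dense_block("rs")
    G_sr = part.dense_block("sr")
    G_ss = part.dense_block("ss")
    X = np.linalg.solve(np.eye(part.N_s) - G_ss, G_sr)
    return G_rr + G_rs @ X


def save_reduced(rgm: ReducedGoogleMatrix, outdir, prefix: str = "reduced") -> list[str]:
    """Write the components as labeled TSV matrices plus a JSON sidecar.

    Matrix convention: row = target node, column = source node (column-
    stochastic, matching the in-memory arrays).
    """
    import pathlib

    import pandas as pd

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    labels = rgm.subset_labels
    for name, M in [
        ("G_rr", rgm.G_rr), ("G_pr", rgm.G_pr), ("G_qr", rgm.G_qr),
        ("G_qrd", rgm.G_qrd), ("G_qrnd", rgm.G_qrnd),
    ]:
        path = outdir / f"{prefix}.{name}.tsv"
        pd.DataFrame(M, index=labels, columns=labels).to_csv(path, sep="\t")
        written.append(str(path))
    sidecar = outdir / f"{prefix}.json"
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "alpha": rgm.alpha,
                "N": rgm.N,
                "N_r": rgm.N_r,
                "lambda_c": rgm.lambda_c,
                "one_minus_lambda_c": rgm.one_minus_lambda_c,
                "W_rr": rgm.W_rr,
                "W_pr": rgm.W_pr,
                "W_qr": rgm.W_qr,
                "negative_weight": rgm.negative_weight,
                "n_series_terms": rgm.n_series_terms,
            },
            fh,
            indent=2,
        )
    written.append(str(sidecar))
    return written
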