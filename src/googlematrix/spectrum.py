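"""Leading complex spectrum of the Google matrix and eigenvector localization.

The right eigenvectors of ``G`` satisfy ``G psi_i = lambda_i psi_i``.  The
PageRank eigenvector belongs to ``lambda_0 = 1``; every other eigenvalue of
``G`` equals ``alpha`` times the corresponding eigenvalue of ``S`` (the
teleportation term only shifts the subspace orthogonal to the uniform left
eigenvector), so the non-leading spectrum lives inside the disk of radius
``alpha``.  Clusters of large-|lambda| eigenvalues flag weakly coupled node
communities in which the random walk is trapped for a finite time.

Localization of an eigenvector is measured by the inverse participation
ratio (IPR)

    xi = (sum_n |psi_n|^2)^2 / sum_n |psi_n|^4,

the effective number of nodes supporting the vector: 1 for a single-site
spike, N for a uniform vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .google import GoogleModel

__all__ = ["SpectrumResult", "leading_spectrum", "ipr"]


@dataclass
class SpectrumResult:
    """Eigenvalues ordered by decreasing modulus, eigenvectors and IPRs."""

    eigenvalues: np.ndarray  # complex, |lambda| descending
    eigenvectors: np.ndarray  # columns, matching order
    ipr: np.ndarray

    def to_frame(self):
        import pandas as pd

        lam = self.eigenvalues
        return pd.DataFrame(
            {
                "index": np.arange(len(lam)),
                "re_lambda": lam.real,
                "im_lambda": lam.imag,
                "abs_lambda": np.abs(lam),
                "ipr": self.ipr,
            }
        )


def ipr(psi: np.ndarray) -> float:
    """Inverse participation ratio of an amplitude vector.

    Scale-invariant; equals the support size for flat vectors.  Computed on
    the L2-normalized amplitudes: ``xi = 1 / sum |psi_hat|^4``.
    """
    psi = np.asarray(psi)
    norm2 = np.sum(np.abs(psi) ** 2)
    if norm2 == 0:
        raise ValueError("IPR undefined for the zero vector")
    p = np.abs(psi) ** 2 / norm2
    return float(1.0 / np.sum(p**2))


def _fix_phase(vec: np.ndarray) -> np.ndarray:
    """Rotate so the largest-modulus component is real and positive."""
    i = int(np.argmax(np.abs(vec)))
    phase = vec[i] / abs(vec[i])
    return vec / phase


def leading_spectrum(model: GoogleModel, k: int, tol: float = 1e-10) -> SpectrumResult:
    """k largest-modulus eigenpairs of the (non-symmetric) G operator.

    Uses implicitly restarted Arnoldi on the matrix-free G for large
    networks, with a dense fallback when k is too close to N for ARPACK.
    Each returned pair satisfies ``||G psi - lambda psi||_2 < 1e-8``.
    """
    N = model.N
    if not 1 <= k < N:
        raise ValueError(f"need 1 <= k < N, got k={k}, N={N}")

    if N <= 200 or k >= N - 2:
        lam, vecs = np.linalg.eig(model.dense_G())
    else:
        op = spla.LinearOperator((N, N), matvec=model.apply_G, dtype=float)
        last_err: Exception | None = None
        lam = vecs = None
        for ncv in (max(2 * k + 1, 20), max(4 * k + 1, 40)):
            try:
                lam, vecs = spla.eigs(op, k=k, which="LM", tol=tol, ncv=min(ncv, N - 1))
                break
            except spla.ArpackNoConvergence as err:  # retry with a larger subspace
                last_err = err
        if lam is None:
            raise RuntimeError(f"Arnoldi failed to converge for k={k}") from last_err

    order = np.argsort(-np.abs(lam))[:k]
    lam = lam[order]
    vecs = vecs[:, order]
    vecs = np.column_stack([_fix_phase(vecs[:, i]) for i in range(vecs.shape[1])])

    for i in range(k):
        resid = np.linalg.norm(model.apply_G(vecs[:, i].real) + 1j * model.apply_G(vecs[:, i].imag)
                               - lam[i] * vecs[:, i])
        if resid > 1e-8 * max(1.0, np.linalg.norm(vecs[:, i])):
            raise RuntimeError(f"eigenpair {i} residual {resid:.2e} exceeds 1e-8")

    iprs = np.array([ipr(vecs[:, i]) for i in range(k)])
    return SpectrumResult(lam, vecs, iprs)
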