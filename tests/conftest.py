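"""Shared fixtures and independent dense oracles.

The oracle helpers here build the Google matrix and its blocks directly
from the edge list with plain numpy, without going through the package's
matrix-free code paths, so tests compare two genuinely independent routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from googlematrix import DirectedNetwork


def dense_google_oracle(net: DirectedNetwork, alpha: float = 0.85) -> np.ndarray:
    """Dense G built straight from the edge list: A -> S (uniform dangling) -> G."""
    n = net.N
    idx = {lab: i for i, lab in enumerate(net.node_labels)}
    A = np.zeros((n, n))
    for e in net.edges:
        A[idx[e.target], idx[e.source]] = 1.0
    k_out = A.sum(axis=0)
    S = np.zeros((n, n))
    for j in range(n):
        S[:, j] = A[:, j] / k_out[j] if k_out[j] > 0 else 1.0 / n
    return alpha * S + (1.0 - alpha) / n


def dense_S_oracle(net: DirectedNetwork) -> np.ndarray:
    n = net.N
    G = dense_google_oracle(net, alpha=0.85)
    return (G - 0.15 / n) / 0.85


def pagerank_oracle(net: DirectedNetwork, alpha: float = 0.85) -> np.ndarray:
    """PageRank from a dense eigendecomposition (eigenvalue-1 eigenvector)."""
    G = dense_google_oracle(net, alpha)
    lam, vecs = np.linalg.eig(G)
    i = int(np.argmin(np.abs(lam - 1.0)))
    v = np.real(vecs[:, i])
    return v / v.sum()


def ring_network(n: int) -> DirectedNetwork:
    labels = [f"R{i}" for i in range(n)]
    net = DirectedNetwork(labels)
    for i in range(n):
        net.add_edge(labels[i], labels[(i + 1) % n])
    return net


@pytest.fixture
def toy4() -> DirectedNetwork:
    """4 nodes, mixed in/out degrees, one dangling node (D)."""
    net = DirectedNetwork(["A", "B", "C", "D"])
    for s, t in [("A", "B"), ("A", "C"), ("B", "C"), ("C", "A"), ("B", "D")]:
        net.add_edge(s, t)
    return net


@pytest.fixture
def toy6() -> DirectedNetwork:
    """6 nodes with a cycle, a branch and a dangling sink."""
    net = DirectedNetwork(list("UVWXYZ"))
    for s, t in [("U", "V"), ("V", "W"), ("W", "U"), ("W", "X"), ("X", "Y"),
                 ("Y", "Z"), ("U", "X"), ("V", "Z")]:
        net.add_edge(s, t)
    return net
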