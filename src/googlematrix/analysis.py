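"""Two-condition rank comparison, hidden-interaction inference and subnetwork accounting.

The "normal" vs "cancer" style of analysis: compute global ranks and reduced
Google matrices under two network conditions sharing a node subset, then

* compare PageRank/CheiRank indexes node-by-node via decimal log-ratios,
* threshold the off-diagonal hidden component ``G_qrnd`` to call indirect
  interactions and classify them as common / emergent / disappearing
  between the conditions,
* rank subset nodes by the leading eigenvector of the reduced matrix
  ("local subnetwork PageRank"),
* account for connectivity gains contributed by hidden links, and
* explain individual hidden links by shortest / second-shortest directed
  paths through the global network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .google import RankResult, rank_indexes
from .network import DirectedNetwork
from .reduced import ReducedGoogleMatrix

__all__ = [
    "RankComparison",
    "HiddenInteraction",
    "HiddenInteractionSet",
    "ConnectivitySummary",
    "compare_ranks",
    "infer_hidden",
    "local_pagerank_ranks",
    "connectivity_summary",
    "short_paths",
    "subset_pagerank_mass",
]


@dataclass
class RankComparison:
    """Per-node decimal log-ratios of rank indexes between conditions A and B.

    ``log_ratio_K[i] = log10(K_B / K_A)`` for common node i: positive means
    the node's PageRank *worsened* (index grew) in condition B.  Node sets
    deviating by more than 1 or 2 standard deviations are pre-selected per
    axis and tail for downstream enrichment-style exports.
    """

    node_labels: list[str]
    log_ratio_K: np.ndarray
    log_ratio_K_star: np.ndarray
    sigma_K: float
    sigma_K_star: float
    selections: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": self.node_labels,
                "log10_K_ratio": self.log_ratio_K,
                "log10_Kstar_ratio": self.log_ratio_K_star,
            }
        )


@dataclass
class HiddenInteraction:
    source: str
    target: str
    score: float  # G_qrnd value in condition A (or B for emergent-only pairs)
    score_b: float | None
    classification: str  # common | emergent_in_B | disappearing_in_B


@dataclass
class HiddenInteractionSet:
    interactions: list[HiddenInteraction]
    threshold: float
    top_k: int | None

    def by_class(self, classification: str) -> list[HiddenInteraction]:
        return [h for h in self.interactions if h.classification == classification]

    def pairs(self) -> set[tuple[str, str]]:
        return {(h.source, h.target) for h in self.interactions}

    def __len__(self) -> int:
        return len(self.interactions)


@dataclass
class ConnectivitySummary:
    lcc_size: int
    n_connected: int  # nodes in components of size >= 2
    n_orphan: int
    lcc_size_with_hidden: int | None = None
    lcc_gain: int | None = None


def compare_ranks(rank_a: RankResult, rank_b: RankResult) -> RankComparison:
    """Decimal log-ratios of K and K* on the common node set of two conditions.

    Selections at +/-1 sigma and +/-2 sigma are computed per axis with both
    tails kept separately (keys like ``"K+2sigma"`` and ``"K-2sigma"``).
    Swapping A and B negates every log-ratio.
    """
    common = [lab for lab in rank_a.node_labels if lab in set(rank_b.node_labels)]
    if not common:
        raise ValueError("the two rank results share no nodes")
    ia = {lab: i for i, lab in enumerate(rank_a.node_labels)}
    ib = {lab: i for i, lab in enumerate(rank_b.node_labels)}
    ka = np.array([rank_a.K[ia[lab]] for lab in common], dtype=float)
    kb = np.array([rank_b.K[ib[lab]] for lab in common], dtype=float)
    lr_k = np.log10(kb / ka)
    if rank_a.K_star is None or rank_b.K_star is None:
        raise ValueError("both rank results need CheiRank indexes (K_star)")
    ksa = np.array([rank_a.K_star[ia[lab]] for lab in common], dtype=float)
    ksb = np.array([rank_b.K_star[ib[lab]] for lab in common], dtype=float)
    lr_ks = np.log10(ksb / ksa)

    sig_k = float(np.std(lr_k))
    sig_ks = float(np.std(lr_ks))
    labels = np.array(common)
    selections: dict[str, list[str]] = {}
    for axis, values, sig in (("K", lr_k, sig_k), ("Kstar", lr_ks, sig_ks)):
        for n_sig in (1, 2):
            selections[f"{axis}+{n_sig}sigma"] = list(labels[values > n_sig * sig])
            selections[f"{axis}-{n_sig}sigma"] = list(labels[values < -n_sig * sig])
    return RankComparison(common, lr_k, lr_ks, sig_k, sig_ks, selections)


def infer_hidden(
    rgm_a: ReducedGoogleMatrix,
    rgm_b: ReducedGoogleMatrix | None = None,
    threshold: float = 0.01,
    top_k: int | None = None,
) -> HiddenInteractionSet:
    """Call hidden interactions from the off-diagonal hidden component.

    A directed pair (source j -> target i, distinct) is called when
    ``G_qrnd[i, j] > threshold``.  The diagonal (return probability of a
    single node) is never reported as an interaction.  With a second
    condition, pairs are classified ``common`` (called in both),
    ``emergent_in_B`` or ``disappearing_in_B``; ``top_k`` truncates each
    class by descending score.
    """
    if rgm_b is not None and rgm_b.subset_labels != rgm_a.subset_labels:
        raise ValueError("the two reduced matrices index different subsets")
    labels = rgm_a.subset_labels
    qa = rgm_a.G_qrnd
    qb = rgm_b.G_qrnd if rgm_b is not None else None

    interactions: list[HiddenInteraction] = []
    n = len(labels)
    for i in range(n):  # target
        for j in range(n):  # source
            if i == j:
                continue
            a_hit = qa[i, j] > threshold
            b_hit = qb is not None and qb[i, j] > threshold
            if qb is None:
                if a_hit:
                    interactions.append(
                        HiddenInteraction(labels[j], labels[i], float(qa[i, j]), None, "common")
                    )
                continue
            if a_hit and b_hit:
                cls = "common"
            elif a_hit:
                cls = "disappearing_in_B"
            elif b_hit:
                cls = "emergent_in_B"
            else:
                continue
            score = float(qa[i, j]) if a_hit else float(qb[i, j])
            interactions.append(
                HiddenInteraction(labels[j], labels[i], score, float(qb[i, j]), cls)
            )

    if top_k is not None:
        kept: list[HiddenInteraction] = []
        for cls in ("common", "emergent_in_B", "disappearing_in_B"):
            members = sorted(
                (h for h in interactions if h.classification == cls),
                key=lambda h: (-h.score, h.source, h.target),
            )
            kept.extend(members[:top_k])
        interactions = kept
    interactions.sort(key=lambda h: (-h.score, h.source, h.target))
    return HiddenInteractionSet(interactions, threshold, top_k)


def local_pagerank_ranks(rgm: ReducedGoogleMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Local subnetwork PageRank from the reduced matrix.

    Returns ``(P_local, K_local)``: the leading (eigenvalue-1) right
    eigenvector of ``G_R = G_rr + G_pr + G_qr`` normalized to sum one, and
    its 1-based rank indexes with the global lexicographic tie-break.  By
    the fixed-point property this reproduces the global PageRank restricted
    to the subset, up to normalization.
    """
    G_R = rgm.G_R
    lam, vecs = np.linalg.eig(G_R)
    i = int(np.argmin(np.abs(lam - 1.0)))
    v = np.real(vecs[:, i])
    if v.sum() < 0:
        v = -v
    P_local = v / v.sum()
    K_local = rank_indexes(P_local, rgm.subset_labels)
    return P_local, K_local


def connectivity_summary(
    nodes: list[str],
    direct_edges: list[tuple[str, str]],
    hidden_edges: list[tuple[str, str]] | None = None,
) -> ConnectivitySummary:
    """Weakly connected component accounting among a node list.

    Direction is ignored for membership.  With ``hidden_edges`` supplied the
    summary also reports how many more nodes the hidden links pull into the
    largest connected component.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((s, t) for s, t in direct_edges if s in g and t in g)
    comps = [c for c in nx.connected_components(g)]
    lcc = max((len(c) for c in comps), default=0)
    orphan = sum(1 for c in comps if len(c) == 1)
    connected = sum(len(c) for c in comps if len(c) >= 2)
    summary = ConnectivitySummary(lcc, connected, orphan)
    if hidden_edges is not None:
        g2 = g.copy()
        g2.add_edges_from((s, t) for s, t in hidden_edges if s in g2 and t in g2)
        lcc2 = max((len(c) for c in nx.connected_components(g2)), default=0)
        summary.lcc_size_with_hidden = lcc2
        summary.lcc_gain = lcc2 - lcc
    return summary


def short_paths(
    net: DirectedNetwork, src: str, dst: str
) -> tuple[list[list[str]], list[list[str]]]:
    """All shortest and all second-shortest simple directed paths src -> dst.

    Second-shortest means every simple path of length exactly one more than
    the shortest — the lengths that become shortest when an edge of a
    shortest path is removed.  Returns ``([], [])`` when dst is unreachable.
    """
    for lab in (src, dst):
        if lab not in net:
            raise KeyError(f"{lab!r} not in network")
    g = nx.DiGraph()
    g.add_nodes_from(net.node_labels)
    g.add_edges_from((e.source, e.target) for e in net.edges)
    if not nx.has_path(g, src, dst):
        return [], []
    shortest = [list(p) for p in nx.all_shortest_paths(g, src, dst)]
    L = len(shortest[0]) - 1
    second = [
        list(p)
        for p in nx.all_simple_paths(g, src, dst, cutoff=L + 1)
        if len(p) - 1 == L + 1
    ]
    if src == dst:
        # networkx treats src==dst simple paths as empty; fall back to cycles
        shortest, second = [[src]], []
    return shortest, second


def subset_pagerank_mass(rank: RankResult, subset: list[str]) -> float:
    """Sigma_P: total global PageRank probability carried by the subset.

    Approximately equals ``1 - lambda_c`` of the corresponding scattering
    block — a useful consistency diagnostic for the reduced computation.
    """
    idx = {lab: i for i, lab in enumerate(rank.node_labels)}
    return float(sum(rank.P[idx[lab]] for lab in subset if lab in idx))
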