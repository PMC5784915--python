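"""Reading, merging and validating directed interaction networks.

Networks are exchanged as SIF (simple interaction format) text: one edge per
line, ``source interaction target``, whitespace- or tab-separated.  Two-token
lines are read as ``source target`` with an empty interaction tag.  Lines
starting with ``#`` are comments.  Gene sets are plain text, one label per
line, ``#`` comments ignored.

The in-memory container :class:`DirectedNetwork` keeps one adjacency entry
per ordered ``(source, target)`` pair: duplicate edges (repeated lines, or
the same pair occurring in several layers or with several interaction types)
collapse to a single edge whose interaction/layer tags are accumulated as
metadata.  Interaction signs never enter any matrix; they are metadata only.
Self-loops are legitimate edges and count toward out-degree.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DirectedNetwork",
    "GeneSet",
    "SifParseError",
    "read_sif",
    "write_sif",
    "merge_networks",
    "read_gene_set",
    "map_gene_set",
]


class SifParseError(ValueError):
    """Raised for malformed SIF lines; the message names the line number."""


@dataclass
class Edge:
    source: str
    target: str
    tags: list[tuple[str, str]] = field(default_factory=list)
    """Accumulated ``(interaction_tag, layer_tag)`` pairs for this ordered pair."""


class DirectedNetwork:
    """A labeled directed graph with deduplicated edges.

    Parameters
    ----------
    node_labels:
        Unique node labels, in insertion order.  Index in this list is the
        node's integer id everywhere in the package.
    edges:
        ``(source_label, target_label, interaction_tag, layer_tag)`` tuples.
        Duplicate ``(source, target)`` pairs are collapsed; their tags are
        kept as a metadata list on the single surviving edge.
    """

    def __init__(
        self,
        node_labels: Iterable[str] = (),
        edges: Iterable[tuple[str, str, str, str]] = (),
    ) -> None:
        self.node_labels: list[str] = []
        self._index: dict[str, int] = {}
        self._edges: dict[tuple[str, str], Edge] = {}
        for lab in node_labels:
            self.add_node(lab)
        for src, dst, inter, layer in edges:
            self.add_edge(src, dst, inter, layer)

    # -- construction -----------------------------------------------------

    def add_node(self, label: str) -> int:
        idx = self._index.get(label)
        if idx is None:
            idx = len(self.node_labels)
            self._index[label] = idx
            self.node_labels.append(label)
        return idx

    def add_edge(self, source: str, target: str, interaction: str = "", layer: str = "") -> None:
        self.add_node(source)
        self.add_node(target)
        key = (source, target)
        edge = self._edges.get(key)
        if edge is None:
            self._edges[key] = Edge(source, target, [(interaction, layer)])
        else:
            edge.tags.append((interaction, layer))

    def remove_edge(self, source: str, target: str) -> None:
        """Drop the edge for an ordered pair if present; nodes are kept."""
        self._edges.pop((source, target), None)

    # -- basic queries -----------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self._edges

    def index_of(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DirectedNetwork(N={self.N}, edges={self.n_edges})"

    # -- matrix views ------------------------------------------------------

    def adjacency(self) -> sp.csr_matrix:
        """0/1 adjacency ``A[i, j] = 1`` iff node ``j`` points to node ``i``.

        Column index is the *source*, row index the *target*, matching the
        column-stochastic convention used throughout the package.
        """
        rows = [self._index[e.target] for e in self._edges.values()]
        cols = [self._index[e.source] for e in self._edges.values()]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.N, self.N))

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.N, dtype=np.int64)
        for e in self._edges.values():
            deg[self._index[e.source]] += 1
        return deg

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.N, dtype=np.int64)
        for e in self._edges.values():
            deg[self._index[e.target]] += 1
        return deg

    def reversed(self) -> "DirectedNetwork":
        """The same network with every edge direction inverted."""
        rev = DirectedNetwork(self.node_labels)
        for e in self._edges.values():
            for inter, layer in e.tags:
                rev.add_edge(e.target, e.source, inter, layer)
        return rev


@dataclass
class GeneSet:
    """A named list of unique gene/protein labels."""

    name: str
    labels: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        deduped = []
        for lab in self.labels:
            if lab not in seen:
                seen.add(lab)
                deduped.append(lab)
        self.labels = deduped

    def __len__(self) -> int:
        return len(self.labels)


# -- SIF I/O ---------------------------------------------------------------


def _parse_sif(handle: io.TextIOBase, layer_tag: str, name: str) -> DirectedNetwork:
    net = DirectedNetwork()
    n_lines = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 1:
            raise SifParseError(f"{name}: line {lineno}: expected >=2 tokens, got 1: {line!r}")
        n_lines += 1
        if len(tokens) == 2:
            src, dst, inter = tokens[0], tokens[1], ""
        else:
            # SIF allows several targets per line: source interaction t1 t2 ...
            src, inter = tokens[0], tokens[1]
            for dst in tokens[2:]:
                net.add_edge(src, dst, inter, layer_tag)
            continue
        net.add_edge(src, dst, inter, layer_tag)
    if n_lines == 0:
        warnings.warn(f"{name}: no edges found; returning empty network", stacklevel=3)
    return net


def read_sif(path, layer_tag: str = "") -> DirectedNetwork:
    """Read a SIF file into a :class:`DirectedNetwork`.

    Duplicate ``(source, target)`` pairs collapse to one edge; interaction
    tags are preserved as metadata.  Direction is first token -> last token.
    """
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_sif(fh, layer_tag, str(path))


def write_sif(net: DirectedNetwork, path, header: Sequence[str] = ()) -> None:
    """Write one line per deduplicated edge; ``header`` lines become ``#`` comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for e in net.edges:
            inter = e.tags[0][0] or "interacts"
            fh.write(f"{e.source}\t{inter}\t{e.target}\n")


def merge_networks(nets: Sequence[DirectedNetwork]) -> DirectedNetwork:
    """Union of node sets and (deduplicated) edge sets; layer tags kept.

    Mirrors merging a signaling SIF with one or more transcriptional-layer
    SIFs by simple concatenation.
    """
    if not nets:
        raise ValueError("merge_networks requires at least one network")
    merged = DirectedNetwork()
    for net in nets:
        for lab in net.node_labels:
            merged.add_node(lab)
        for e in net.edges:
            for inter, layer in e.tags:
                merged.add_edge(e.source, e.target, inter, layer)
    return merged


# -- gene sets --------------------------------------------------------------


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One label per line; ``#`` starts a comment; blank lines ignored."""
    labels = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                labels.append(line)
    return GeneSet(name or str(path), labels)


def map_gene_set(net: DirectedNetwork, gs: GeneSet) -> tuple[list[str], list[str]]:
    """Split a gene set into (present, missing) network labels.

    Matching is exact and case-sensitive; the gene set's order is preserved
    in both outputs.  Both the raw set size and the mapped count matter when
    comparing against published pathway statistics, so callers should report
    both rather than assuming they coincide.
    """
    present = [lab for lab in gs.labels if lab in net]
    missing = [lab for lab in gs.labels if lab not in net]
    return present, missing
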