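"""Reproducible synthetic directed networks with planted structure.

The generators emulate the topology of curated signaling networks at the
scale of SIGNOR (roughly 2400 nodes, 6600 directed links, hence mean
out-degree near 2.7), with three features that matter for Google-matrix
analysis: heavy-tailed out-degrees with a few fan-like hubs (transcription
factors regulating many targets), a controllable fraction of dangling
nodes (terminal effectors with no outgoing links), and — for validating
hidden-link inference — explicitly planted relay chains that connect two
subset nodes only through nodes outside the subset.

Everything is seed-deterministic; fixture metadata is embedded as comment
headers when networks are written to SIF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DirectedNetwork, GeneSet

__all__ = [
    "FixtureSpec",
    "random_network",
    "planted_relay",
    "two_condition_pair",
]


@dataclass
class FixtureSpec:
    """Parameters of the background random-network model."""

    n: int = 100
    mean_out_degree: float = 2.7
    dangling_fraction: float = 0.1
    hub_count: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 <= self.dangling_fraction < 1:
            raise ValueError("dangling_fraction must lie in [0, 1)")
        if self.mean_out_degree >= self.n:
            raise ValueError("mean_out_degree must be smaller than n")
        if self.hub_count + int(round(self.dangling_fraction * self.n)) >= self.n:
            raise ValueError("hubs plus dangling nodes exhaust the network")


def _label(i: int) -> str:
    return f"N{i:05d}"


def random_network(spec: FixtureSpec, layer_tag: str = "signaling") -> DirectedNetwork:
    """Sparse random directed network with hubs and dangling nodes.

    Per-node out-degrees are geometric (heavy-tailed) with the mean of the
    non-hub, non-dangling nodes calibrated so the expected total edge count
    is ``n * mean_out_degree``; hubs draw around ten times the mean
    (fan-like out-neighborhoods); a designated fraction of nodes has no
    outgoing links at all.  Targets are sampled uniformly without
    replacement over all nodes, so self-loops occur at their natural rate
    and there are no multi-edges.  Same seed, same network, byte for byte.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.mean_out_degree
    n_dang = int(round(spec.dangling_fraction * n))
    perm = rng.permutation(n)
    hub_ids = set(perm[: spec.hub_count].tolist())
    dang_ids = set(perm[spec.hub_count: spec.hub_count + n_dang].tolist())
    n_reg = n - spec.hub_count - n_dang
    hub_mean = 10.0 * m
    reg_mean = (n * m - spec.hub_count * hub_mean) / max(n_reg, 1)
    if n_reg > 0 and reg_mean < 1.0:
        raise ValueError("infeasible spec: hubs absorb the whole edge budget")

    net = DirectedNetwork(_label(i) for i in range(n))
    for i in range(n):
        if i in dang_ids:
            continue
        mean = hub_mean if i in hub_ids else reg_mean
        deg = int(rng.geometric(1.0 / mean))  # support {1, 2, ...}, mean `mean`
        deg = min(deg, n)
        targets = rng.choice(n, size=deg, replace=False)
        for t in targets:
            net.add_edge(_label(i), _label(int(t)), "reg", layer_tag)
    return net


def planted_relay(
    n_background: int,
    subset_size: int,
    relay_length: int,
    seed: int = 0,
    spec: FixtureSpec | None = None,
) -> tuple[DirectedNetwork, GeneSet, tuple[str, str]]:
    """Background network plus a hidden relay chain between two subset nodes.

    A directed chain ``r1 -> x_1 -> ... -> x_relay_length -> r2`` is added,
    with the relay nodes outside the subset and no direct ``r1 -> r2`` edge,
    so the only r1-to-r2 route of length <= relay_length + 1 runs through the
    scattering network: the pair must light up in ``G_qrnd``, not ``G_rr``.
    Returns the network, the subset gene set, and the planted (r1, r2) pair.
    """
    if relay_length < 1:
        raise ValueError("relay_length must be >= 1")
    if subset_size < 2:
        raise ValueError("subset_size must be >= 2")
    if subset_size + relay_length > n_background:
        raise ValueError("subset plus relay nodes exceed the background size")
    base = spec or FixtureSpec(n=n_background, seed=seed)
    base = FixtureSpec(
        n=n_background,
        mean_out_degree=base.mean_out_degree,
        dangling_fraction=base.dangling_fraction,
        hub_count=base.hub_count,
        seed=seed,
    )
    net = random_network(base)
    rng = np.random.default_rng(seed + 1)
    subset_ids = rng.choice(n_background, size=subset_size, replace=False)
    subset = [_label(int(i)) for i in subset_ids]
    r1, r2 = subset[0], subset[1]
    relay = [_label(n_background + k) for k in range(relay_length)]
    chain = [r1, *relay, r2]
    for a, b in zip(chain[:-1], chain[1:]):
        net.add_edge(a, b, "relay", "signaling")
    # the planted pair must not be directly linked
    net.remove_edge(r1, r2)
    return net, GeneSet("planted_subset", subset), (r1, r2)


def two_condition_pair(
    base_spec: FixtureSpec,
    rewire_fraction: float,
    seed: int = 0,
    tf_count: int = 5,
    tf_fan_out: int = 10,
) -> tuple[DirectedNetwork, DirectedNetwork]:
    """A "normal"/"cancer" style network pair sharing a fixed signaling layer.

    Condition A is the base network (layer ``signaling``) plus a
    transcriptional layer: ``tf_count`` regulator nodes each fanning out to
    ``tf_fan_out`` uniformly chosen targets (layer ``transcription``).
    Condition B keeps the signaling layer bit-identical and rewires each
    transcription-layer edge independently with probability
    ``rewire_fraction`` (the target is resampled to a different node).
    """
    if not 0 <= rewire_fraction <= 1:
        raise ValueError("rewire_fraction must lie in [0, 1]")
    base_spec.validate()
    signaling = random_network(base_spec)
    rng = np.random.default_rng(seed + 10_000)
    n = base_spec.n
    tfs = rng.choice(n, size=min(tf_count, n), replace=False)
    tx_edges: list[tuple[str, str]] = []
    for tf in tfs:
        targets = rng.choice(n, size=min(tf_fan_out, n), replace=False)
        tx_edges.extend((_label(int(tf)), _label(int(t))) for t in targets)

    def build(edges: list[tuple[str, str]]) -> DirectedNetwork:
        net = DirectedNetwork(signaling.node_labels)
        for e in signaling.edges:
            for inter, layer in e.tags:
                net.add_edge(e.source, e.target, inter, layer)
        for s, t in edges:
            net.add_edge(s, t, "tx", "transcription")
        return net

    net_a = build(tx_edges)
    fan: dict[str, set[str]] = {}
    for s, t in tx_edges:
        fan.setdefault(s, set()).add(t)
    rewired: list[tuple[str, str]] = []
    for s, t in tx_edges:
        if rng.random() < rewire_fraction:
            # resample outside the regulator's original fan so a rewired
            # edge never coincides with any condition-A transcription edge
            new_t = t
            while new_t in fan[s]:
                new_t = _label(int(rng.integers(n)))
            rewired.append((s, new_t))
        else:
            rewired.append((s, t))
    net_b = build(rewired)
    return net_a, net_b
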