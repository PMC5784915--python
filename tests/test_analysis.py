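"""Rank comparison, hidden-interaction calling, connectivity and paths."""

import numpy as np
import pytest

from googlematrix import (
    DirectedNetwork,
    FixtureSpec,
    build_transition,
    compare_ranks,
    compute_reduced,
    connectivity_summary,
    full_ranking,
    infer_hidden,
    local_pagerank_ranks,
    pagerank,
    random_network,
    short_paths,
)


class TestCompareRanks:
    def test_identical_networks_give_zero_log_ratios(self, toy6):
        r = full_ranking(toy6)
        cmpres = compare_ranks(r, r)
        assert np.all(cmpres.log_ratio_K == 0.0)
        assert np.all(cmpres.log_ratio_K_star == 0.0)

    def test_direct_arithmetic_of_log_ratio(self):
        # node with K_A = 10, K_B = 1000 -> log10 ratio = 2
        assert np.isclose(np.log10(1000 / 10), 2.0)
        net_a = DirectedNetwork(edges=[("A", "B", "", ""), ("B", "A", "", "")])
        ra = full_ranking(net_a)
        cmpres = compare_ranks(ra, ra)
        assert cmpres.sigma_K == 0.0

    def test_antisymmetry_under_condition_swap(self):
        from googlematrix import two_condition_pair

        net_a, net_b = two_condition_pair(FixtureSpec(n=60, seed=3), 0.5, seed=3)
        ra, rb = full_ranking(net_a), full_ranking(net_b)
        fwd = compare_ranks(ra, rb)
        bwd = compare_ranks(rb, ra)
        assert np.allclose(fwd.log_ratio_K, -bwd.log_ratio_K)
        assert np.allclose(fwd.log_ratio_K_star, -bwd.log_ratio_K_star)

    def test_deleting_in_edges_worsens_pagerank(self):
        net_a = random_network(FixtureSpec(n=50, seed=4))
        victim = max(net_a.node_labels, key=lambda lab: net_a.in_degrees()[net_a.index_of(lab)])
        net_b = DirectedNetwork(net_a.node_labels)
        for e in net_a.edges:
            if e.target != victim:
                net_b.add_edge(e.source, e.target)
        cmpres = compare_ranks(full_ranking(net_a), full_ranking(net_b))
        i = cmpres.node_labels.index(victim)
        assert cmpres.log_ratio_K[i] > 0  # K index grew: less central in B

    def test_sigma_selections_cover_both_tails(self):
        from googlematrix import two_condition_pair

        net_a, net_b = two_condition_pair(FixtureSpec(n=80, seed=5), 0.8, seed=5)
        cmpres = compare_ranks(full_ranking(net_a), full_ranking(net_b))
        for key in ("K+1sigma", "K-1sigma", "K+2sigma", "K-2sigma",
                    "Kstar+1sigma", "Kstar-1sigma", "Kstar+2sigma", "Kstar-2sigma"):
            assert key in cmpres.selections
        assert set(cmpres.selections["K+2sigma"]) <= set(cmpres.selections["K+1sigma"])

    def test_disjoint_networks_rejected(self):
        a = full_ranking(DirectedNetwork(edges=[("A", "B", "", ""), ("B", "A", "", "")]))
        b = full_ranking(DirectedNetwork(edges=[("X", "Y", "", ""), ("Y", "X", "", "")]))
        with pytest.raises(ValueError):
            compare_ranks(a, b)


@pytest.fixture(scope="module")
def rgm_pair():
    net = random_network(FixtureSpec(n=60, seed=40))
    model = build_transition(net)
    subset = net.node_labels[:8]
    rgm = compute_reduced(model, subset)
    # second condition: drop the out-edges of one non-subset node
    net_b = DirectedNetwork(net.node_labels)
    cut = net.node_labels[30]
    for e in net.edges:
        if e.source != cut:
            net_b.add_edge(e.source, e.target)
    rgm_b = compute_reduced(build_transition(net_b), subset)
    return rgm, rgm_b


class TestInferHidden:
    def test_single_condition_all_common(self, rgm_pair):
        rgm, _ = rgm_pair
        hs = infer_hidden(rgm, threshold=0.0)
        assert all(h.classification == "common" for h in hs.interactions)

    def test_identical_conditions_have_no_emergent_or_disappearing(self, rgm_pair):
        rgm, _ = rgm_pair
        hs = infer_hidden(rgm, rgm, threshold=0.001)
        assert hs.by_class("emergent_in_B") == []
        assert hs.by_class("disappearing_in_B") == []

    def test_threshold_zero_returns_all_positive_offdiagonal(self, rgm_pair):
        rgm, _ = rgm_pair
        hs = infer_hidden(rgm, threshold=0.0)
        q = rgm.G_qrnd
        expected = int(((q > 0) & ~np.eye(rgm.N_r, dtype=bool)).sum())
        assert len(hs) == expected

    def test_monotone_in_threshold(self, rgm_pair):
        rgm, rgm_b = rgm_pair
        lo = infer_hidden(rgm, rgm_b, threshold=0.001)
        hi = infer_hidden(rgm, rgm_b, threshold=0.01)
        assert hi.pairs() <= lo.pairs()

    def test_diagonal_never_reported(self, rgm_pair):
        rgm, _ = rgm_pair
        hs = infer_hidden(rgm, threshold=0.0)
        assert all(h.source != h.target for h in hs.interactions)

    def test_top_k_truncates_by_score(self, rgm_pair):
        rgm, rgm_b = rgm_pair
        full = infer_hidden(rgm, rgm_b, threshold=0.0)
        top = infer_hidden(rgm, rgm_b, threshold=0.0, top_k=3)
        for cls in ("common", "emergent_in_B", "disappearing_in_B"):
            full_scores = sorted((h.score for h in full.by_class(cls)), reverse=True)
            top_scores = sorted((h.score for h in top.by_class(cls)), reverse=True)
            assert top_scores == full_scores[:3]

    def test_subset_mismatch_rejected(self, rgm_pair):
        rgm, _ = rgm_pair
        other = random_network(FixtureSpec(n=40, seed=41))
        rgm_other = compute_reduced(build_transition(other), other.node_labels[:5])
        with pytest.raises(ValueError):
            infer_hidden(rgm, rgm_other)


class TestLocalPagerankRanks:
    def test_single_node_subset(self):
        net = random_network(FixtureSpec(n=20, seed=42, hub_count=0))
        rgm = compute_reduced(build_transition(net), [net.node_labels[0]])
        P_local, K_local = local_pagerank_ranks(rgm)
        assert np.isclose(P_local[0], 1.0)
        assert K_local.tolist() == [1]

    def test_order_matches_global_pagerank_restriction(self):
        net = random_network(FixtureSpec(n=70, seed=43))
        model = build_transition(net)
        subset = net.node_labels[:9]
        rgm = compute_reduced(model, subset)
        P_local, K_local = local_pagerank_ranks(rgm)
        P = pagerank(model).P
        idx = [net.index_of(x) for x in subset]
        P_r = P[idx] / P[idx].sum()
        assert np.abs(P_local - P_r).max() < 1e-8
        # rank order must agree wherever probabilities are not numerically tied
        for i in range(9):
            for j in range(9):
                if P_r[i] - P_r[j] > 1e-6:
                    assert K_local[i] < K_local[j]

    def test_symmetric_tie_broken_lexicographically(self):
        # two-node symmetric cycle: equal probabilities, label order decides
        net = DirectedNetwork(edges=[("B", "A", "", ""), ("A", "B", "", "")])
        rgm = compute_reduced(build_transition(net), ["A", "B"])
        _, K_local = local_pagerank_ranks(rgm)
        assert K_local[rgm.subset_labels.index("A")] == 1


class TestConnectivitySummary:
    def test_star_is_one_component(self):
        edges = [("hub", f"leaf{i}") for i in range(4)]
        s = connectivity_summary(["hub"] + [f"leaf{i}" for i in range(4)], edges)
        assert s.lcc_size == 5
        assert s.n_orphan == 0

    def test_two_pairs_and_isolate(self):
        s = connectivity_summary(
            ["a", "b", "c", "d", "e"], [("a", "b"), ("c", "d")]
        )
        assert s.lcc_size == 2
        assert s.n_connected == 4
        assert s.n_orphan == 1

    def test_hidden_edge_bridges_components(self):
        nodes = ["a", "b", "c", "d", "e"]
        direct = [("a", "b"), ("a", "c"), ("d", "e")]
        s = connectivity_summary(nodes, direct, hidden_edges=[("c", "d")])
        assert s.lcc_size == 3
        assert s.lcc_size_with_hidden == 5
        assert s.lcc_gain == 2  # the smaller component's size

    def test_invariant_under_edge_reversal(self):
        nodes = [f"n{i}" for i in range(8)]
        edges = [("n0", "n1"), ("n2", "n1"), ("n3", "n4"), ("n5", "n6")]
        fwd = connectivity_summary(nodes, edges)
        rev = connectivity_summary(nodes, [(t, s) for s, t in edges])
        assert (fwd.lcc_size, fwd.n_connected, fwd.n_orphan) == (
            rev.lcc_size, rev.n_connected, rev.n_orphan)

    def test_edges_outside_node_list_ignored(self):
        s = connectivity_summary(["a", "b"], [("a", "zz"), ("a", "b")])
        assert s.lcc_size == 2


class TestShortPaths:
    def build(self):
        net = DirectedNetwork()
        for s, t in [("s", "d"), ("s", "m1"), ("m1", "d"), ("s", "m2"),
                     ("m2", "m3"), ("m3", "d")]:
            net.add_edge(s, t)
        return net

    def test_direct_edge_and_two_step_detours(self):
        net = self.build()
        shortest, second = short_paths(net, "s", "d")
        assert shortest == [["s", "d"]]
        assert second == [["s", "m1", "d"]]

    def test_disconnected_pair_is_empty(self):
        net = DirectedNetwork(edges=[("a", "b", "", ""), ("c", "d", "", "")])
        assert short_paths(net, "a", "d") == ([], [])

    def test_direction_respected(self):
        net = DirectedNetwork(edges=[("a", "b", "", "")])
        assert short_paths(net, "b", "a") == ([], [])

    def test_matches_bruteforce_enumeration_on_toy6(self, toy6):
        import itertools

        labels = toy6.node_labels
        pairs = toy6.edge_pairs()

        def brute(src, dst):
            found = {}
            for r in range(2, len(labels) + 1):
                for mids in itertools.permutations([x for x in labels if x not in (src, dst)],
                                                   r - 2):
                    path = [src, *mids, dst]
                    if all((a, b) in pairs for a, b in zip(path[:-1], path[1:])):
                        found.setdefault(len(path) - 1, []).append(path)
            if not found:
                return [], []
            L = min(found)
            return sorted(found[L]), sorted(found.get(L + 1, []))

        for src, dst in [("U", "Z"), ("V", "X"), ("U", "Y")]:
            shortest, second = short_paths(toy6, src, dst)
            b_short, b_second = brute(src, dst)
            assert sorted(shortest) == b_short
            assert sorted(second) == b_second

    def test_unknown_node_rejected(self, toy6):
        with pytest.raises(KeyError):
            short_paths(toy6, "U", "missing")
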