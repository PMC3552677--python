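"""PPI annotation, dual-disease candidate inference, hubs, sub-networks."""

import random

import networkx as nx
import pytest

from comopath import (
    GeneSet,
    InteractionNetwork,
    NodeClass,
    ValidationError,
    annotate_network,
    detect_hubs,
    extract_subnetwork,
    infer_candidates,
    partner_census,
    read_gene_list,
    read_ppi_table,
)


def _net(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractionNetwork(graph=g)


SET1 = GeneSet.from_symbols("d1", ["S1", "S2", "S3", "SB"])
SET2 = GeneSet.from_symbols("d2", ["T1", "T2", "SB"])


class TestAnnotateNetwork:
    def test_star_centre_is_neighbor(self):
        net = annotate_network(_net([("C", "S1"), ("C", "T1")]), SET1, SET2)
        assert net.node_class["C"] is NodeClass.NEIGHBOR
        assert net.node_class["S1"] is NodeClass.SUS1
        assert net.node_class["T1"] is NodeClass.SUS2

    def test_protein_on_both_lists_is_sus_both(self):
        net = annotate_network(_net([("SB", "X")]), SET1, SET2)
        assert net.node_class["SB"] is NodeClass.SUS_BOTH

    def test_unmapped_susceptibility_proteins_dropped(self):
        net = annotate_network(_net([("S1", "X"), ("Y", "Z")]), SET1, SET2)
        assert "S2" not in net.graph
        assert "Y" not in net.graph  # not adjacent to any susceptibility node

    def test_classes_partition_and_neighbors_touch_sus(self):
        net = annotate_network(
            _net([("S1", "X"), ("T1", "X"), ("S2", "T2"), ("X", "W"), ("W", "S3")]),
            SET1,
            SET2,
        )
        classes = net.node_class
        assert set(classes) == set(net.graph.nodes)
        sus = {n for n, c in classes.items() if c.is_susceptibility}
        for n, c in classes.items():
            if c is NodeClass.NEIGHBOR:
                assert sus & set(net.graph.neighbors(n))

    def test_no_mapped_susceptibility_rejected(self):
        with pytest.raises(ValidationError):
            annotate_network(_net([("A", "B")]), SET1, SET2)


class TestInferCandidates:
    def test_single_disease_neighbor_not_emitted(self):
        net = annotate_network(_net([("N1", "S1")]), SET1, SET2)
        assert infer_candidates(net) == []

    def test_toy_graph_degrees(self):
        # N1 touches {S1, S2, T1}; N2 touches {S1} only
        net = annotate_network(
            _net([("N1", "S1"), ("N1", "S2"), ("N1", "T1"), ("N2", "S1")]),
            SET1,
            SET2,
        )
        recs = infer_candidates(net)
        assert [(r.protein, r.deg1, r.deg2) for r in recs] == [("N1", 2, 1)]

    def test_sus_both_partner_counts_toward_both(self):
        net = annotate_network(_net([("N1", "SB")]), SET1, SET2)
        recs = infer_candidates(net)
        assert [(r.protein, r.deg1, r.deg2) for r in recs] == [("N1", 1, 1)]

    def test_min_each_two(self):
        net = annotate_network(
            _net([("N1", "S1"), ("N1", "S2"), ("N1", "T1"), ("N1", "T2"),
                  ("N2", "S1"), ("N2", "T1")]),
            SET1,
            SET2,
        )
        assert {r.protein for r in infer_candidates(net, min_each=1)} == {
            "N1", "N2"
        }
        assert {r.protein for r in infer_candidates(net, min_each=2)} == {"N1"}

    def test_susceptibility_proteins_never_candidates(self):
        # SB touches S1 and T1 but is itself a susceptibility protein
        net = annotate_network(
            _net([("SB", "S1"), ("SB", "T1"), ("N1", "S1"), ("N1", "T1")]),
            SET1,
            SET2,
        )
        assert {r.protein for r in infer_candidates(net)} == {"N1"}

    def test_edge_order_invariance(self, default_truth):
        files = default_truth.files
        gs1 = read_gene_list(files["cluster1"], "c1")
        gs2 = read_gene_list(files["cluster2"], "c2")
        base = read_ppi_table(files["ppi"])
        edges = sorted(base.edges)
        rng = random.Random(5)
        results = []
        for _ in range(3):
            rng.shuffle(edges)
            g = nx.Graph()
            g.add_edges_from(edges)
            net = annotate_network(InteractionNetwork(graph=g), gs1, gs2)
            results.append(infer_candidates(net))
        assert results[0] == results[1] == results[2]


class TestDetectHubs:
    @pytest.mark.parametrize(
        "deg1,deg2,expected", [(5, 5, True), (5, 4, False), (4, 5, False)]
    )
    def test_boundary_inclusive(self, deg1, deg2, expected):
        net = annotate_network(
            _net([("N1", "S1"), ("N1", "T1")]), SET1, SET2
        )
        recs = infer_candidates(net)
        from comopath import CandidateRecord

        cand = [CandidateRecord("X", deg1, deg2)]
        hubs = detect_hubs(cand, h=5)
        assert bool(hubs) is expected
        if hubs:
            assert hubs[0].is_hub
        del recs, net

    def test_hubs_subset_of_candidates(self, default_truth):
        files = default_truth.files
        gs1 = read_gene_list(files["cluster1"], "c1")
        gs2 = read_gene_list(files["cluster2"], "c2")
        net = annotate_network(read_ppi_table(files["ppi"]), gs1, gs2)
        candidates = infer_candidates(net)
        names = {r.protein for r in candidates}
        for h in (1, 2, 5, 9):
            assert {r.protein for r in detect_hubs(candidates, h=h)} <= names


class TestExtractSubnetwork:
    def test_one_candidate_two_partners(self):
        net = annotate_network(
            _net([("N1", "S1"), ("N1", "T1"), ("S2", "T2")]), SET1, SET2
        )
        sub = extract_subnetwork(net, infer_candidates(net))
        assert set(sub.graph.nodes) == {"N1", "S1", "T1"}
        assert sub.n_edges == 2

    def test_shared_partner_appears_once(self):
        net = annotate_network(
            _net([("N1", "S1"), ("N1", "T1"), ("N2", "S1"), ("N2", "T2")]),
            SET1,
            SET2,
        )
        sub = extract_subnetwork(net, infer_candidates(net))
        assert set(sub.graph.nodes) == {"N1", "N2", "S1", "T1", "T2"}

    def test_induced_semantics_keep_candidate_candidate_edges(self):
        net = annotate_network(
            _net([
                ("N1", "S1"), ("N1", "T1"),
                ("N2", "S2"), ("N2", "T2"),
                ("N1", "N2"),          # candidate-candidate adjacency
                ("S1", "T1"),          # susceptibility-susceptibility
            ]),
            SET1,
            SET2,
        )
        sub = extract_subnetwork(net, infer_candidates(net))
        assert ("N1", "N2") in {tuple(sorted(e)) for e in sub.graph.edges}
        assert ("S1", "T1") in {tuple(sorted(e)) for e in sub.graph.edges}
        # classes carry over
        assert sub.node_class["N1"] is NodeClass.NEIGHBOR
        assert sub.node_class["S1"] is NodeClass.SUS1

    def test_empty_candidate_list_rejected(self):
        net = annotate_network(_net([("N1", "S1")]), SET1, SET2)
        with pytest.raises(ValidationError):
            extract_subnetwork(net, [])

    def test_non_neighbor_candidate_rejected(self):
        from comopath import CandidateRecord

        net = annotate_network(_net([("N1", "S1")]), SET1, SET2)
        with pytest.raises(ValidationError):
            extract_subnetwork(net, [CandidateRecord("S1", 1, 1)])


class TestPartnerCensus:
    def test_single_disease_neighbor_aggregates(self):
        net = annotate_network(
            _net([("N1", "S1"), ("N1", "S2")]), SET1, SET2
        )
        census = partner_census(net)
        assert census.aggregates == {
            "deg1_ge_1": 1, "deg2_ge_1": 0,
            "deg1_ge_2": 1, "deg2_ge_2": 0,
            "dual": 0,
        }

    def test_empty_neighbor_set(self):
        net = annotate_network(_net([("S1", "T1")]), SET1, SET2)
        census = partner_census(net)
        assert all(v == 0 for v in census.aggregates.values())

    def test_aggregates_match_brute_force_recount(self, default_truth):
        files = default_truth.files
        gs1 = read_gene_list(files["cluster1"], "c1")
        gs2 = read_gene_list(files["cluster2"], "c2")
        net = annotate_network(read_ppi_table(files["ppi"]), gs1, gs2)
        census = partner_census(net)
        # independent recount straight from the graph
        recount = {"deg1_ge_1": 0, "deg2_ge_1": 0,
                   "deg1_ge_2": 0, "deg2_ge_2": 0, "dual": 0}
        for node, data in net.graph.nodes(data=True):
            if data["node_class"] != "neighbor":
                continue
            d1 = sum(
                1 for nb in net.graph.neighbors(node)
                if net.graph.nodes[nb]["node_class"] in ("sus1", "sus_both")
            )
            d2 = sum(
                1 for nb in net.graph.neighbors(node)
                if net.graph.nodes[nb]["node_class"] in ("sus2", "sus_both")
            )
            for x in (1, 2):
                recount["deg1_ge_%d" % x] += d1 >= x
                recount["deg2_ge_%d" % x] += d2 >= x
            recount["dual"] += d1 >= 1 and d2 >= 1
        assert census.aggregates == recount
        assert census.aggregates["dual"] == len(infer_candidates(net))
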