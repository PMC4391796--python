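"""Character recoding and median-joining network construction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from barcodegap.delimit import LineagePartition
from barcodegap.distances import step_count_pair
from barcodegap.mjnetwork import (CharacterMatrix, Character, encode_characters,
                                  lineage_separation, median_joining)

from conftest import make_aligned


def binary_cm(haplos: dict[str, str]) -> CharacterMatrix:
    n_chars = len(next(iter(haplos.values())))
    return CharacterMatrix(
        ids=list(haplos),
        characters=[Character("substitution_site", (i,))
                    for i in range(n_chars)],
        states={k: np.array([int(c) for c in v]) for k, v in haplos.items()})


class TestEncodeCharacters:
    def test_multicolumn_gap_run_is_one_step(self):
        aset = make_aligned({"a": "ACGTACGTAC", "b": "AC-----TAC"})
        cm = encode_characters(aset)
        indels = [c for c in cm.characters if c.kind == "indel_block"]
        assert len(indels) == 1
        assert indels[0].definition == (2, 7)
        assert step_count_pair("a", "b", cm) == 1

    def test_three_substitutions_three_steps(self):
        aset = make_aligned({"a": "ACGTACGTAC", "b": "TCGAACGTAG"})
        cm = encode_characters(aset)
        assert all(c.kind == "substitution_site" for c in cm.characters)
        assert len(cm.characters) == 3
        assert step_count_pair("a", "b", cm) == 3

    def test_invariant_alignment_no_characters(self):
        aset = make_aligned({"a": "ACGTAC", "b": "ACGTAC", "c": "ACGTAC"})
        assert encode_characters(aset).n_characters == 0

    def test_substitutions_and_indel_combine(self):
        aset = make_aligned({"a": "ACGTACGTAC", "b": "TC-----TAG"})
        cm = encode_characters(aset)
        # 2 substitution steps + 1 indel step
        assert step_count_pair("a", "b", cm) == 3

    def test_structural_annotation_excludes_columns(self):
        aset = make_aligned({"a": "ACGTACGTAC", "b": "ACCAACGTAC"})
        cm = encode_characters(aset, structural_annotations=[(2, 4)])
        kinds = [c.kind for c in cm.characters]
        assert kinds.count("structural") == 1
        # the two differing columns fall inside the annotation: one step
        assert step_count_pair("a", "b", cm) == 1

    def test_overlapping_annotations_rejected(self):
        aset = make_aligned({"a": "ACGTAC", "b": "ACGTAC"})
        with pytest.raises(ValueError, match="overlap"):
            encode_characters(aset, structural_annotations=[(1, 4), (3, 6)])

    def test_unknown_id_raises(self):
        aset = make_aligned({"a": "ACGT", "b": "AGGT"})
        cm = encode_characters(aset)
        with pytest.raises(KeyError, match="nope"):
            step_count_pair("a", "nope", cm)


class TestMedianJoining:
    def test_two_haplotypes_single_weighted_edge(self):
        net = median_joining(binary_cm({"a": "0000", "b": "1111"}))
        g = net.graph
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1
        assert list(g.edges(data="weight"))[0][2] == 4

    def test_median_vector_star(self):
        # 000/110/011: exhaustive Steiner search over {0,1}^3 gives 010
        haplos = {"a": "000", "b": "110", "c": "011"}
        best_cost, best_vec = min(
            (sum(sum(x != y for x, y in zip(v, h)) for h in haplos.values()),
             v)
            for v in itertools.product("01", repeat=3))
        assert best_cost == 3 and "".join(best_vec) == "010"

        net = median_joining(binary_cm(haplos))
        assert len(net.median_nodes) == 1
        median = net.graph.nodes[net.median_nodes[0]]["states"]
        assert tuple(median) == (0, 1, 0)
        assert net.total_weight() == 3
        assert all(w == 1 for _, _, w in net.graph.edges(data="weight"))

    def test_duplicate_haplotypes_collapse_with_multiplicity(self):
        net = median_joining(binary_cm({"a1": "000", "a2": "000",
                                        "b": "011"}))
        node = next(n for n in net.observed_nodes
                    if "a1" in net.members_of(n))
        assert net.graph.nodes[node]["multiplicity"] == 2

    def test_single_haplotype_warns(self):
        with pytest.warns(UserWarning, match="single"):
            net = median_joining(binary_cm({"a": "000", "b": "000"}))
        assert net.graph.number_of_nodes() == 1

    def test_network_connected_and_contains_all_msts(self, rng):
        """Superset property: every MST of the final node set's distance
        graph lies inside the network (exhaustive on <=7 haplotypes)."""
        for _ in range(10):
            n, k = 6, 7
            haplos = {}
            while len(haplos) < n:
                haplos[f"h{len(haplos)}"] = "".join(
                    rng.choice(["0", "1"], size=k))
            net = median_joining(binary_cm(haplos))
            g = net.graph
            assert nx.is_connected(g)
            # complete distance graph over final nodes
            full = nx.Graph()
            states = {node: tuple(g.nodes[node]["states"]) for node in g}
            for u, v in itertools.combinations(g.nodes, 2):
                w = sum(x != y for x, y in zip(states[u], states[v]))
                full.add_edge(u, v, weight=w)
            mst_weight = nx.minimum_spanning_tree(full).size(weight="weight")
            net_edges = set(map(frozenset, g.edges))
            for mst in nx.SpanningTreeIterator(full, weight="weight"):
                if mst.size(weight="weight") > mst_weight:
                    break
                assert all(frozenset(e) in net_edges for e in mst.edges)

    def test_accepted_medians_never_raise_spanning_cost(self, rng):
        """The minimum spanning weight of the node set is non-increasing
        across median acceptance rounds (Steiner improvement property)."""
        for _ in range(10):
            haplos = {}
            while len(haplos) < 5:
                haplos[f"h{len(haplos)}"] = "".join(
                    rng.choice(["0", "1"], size=6))
            net = median_joining(binary_cm(haplos))
            hist = net.mst_weight_history
            assert all(b <= a for a, b in zip(hist, hist[1:]))


class TestLineageSeparation:
    def test_direct_edge_weight(self):
        net = median_joining(binary_cm({"a": "0000000", "b": "1111111"}))
        part = LineagePartition({"a": "L1", "b": "L2"})
        sep = lineage_separation(net, part)
        assert sep.loc["L1", "L2"] == 7
        assert sep.loc["L1", "L1"] == 0

    def test_geodesic_through_median_matches_brute_force(self):
        haplos = {"a": "000000", "b": "111000", "c": "011110"}
        cm = binary_cm(haplos)
        net = median_joining(cm)
        part = LineagePartition({"a": "L1", "b": "L2", "c": "L3"})
        sep = lineage_separation(net, part)
        # brute-force shortest path on the constructed graph
        for x, y, lx, ly in [("a", "b", "L1", "L2"), ("a", "c", "L1", "L3"),
                             ("b", "c", "L2", "L3")]:
            node_of = {s: n for n in net.observed_nodes
                       for s in net.members_of(n)}
            exp = nx.shortest_path_length(net.graph, node_of[x], node_of[y],
                                          weight="weight")
            assert sep.loc[lx, ly] == exp
            # geodesic can never exceed the direct hamming distance
            assert sep.loc[lx, ly] <= cm.hamming(x, y)
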