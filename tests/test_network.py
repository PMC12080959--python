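import numpy as np
import pytest

from upna_ppi import (CapacityError, ConfigurationError, EdgeListParseError,
                      Interactome, canonical_pair, complement_sample,
                      count_four_cycles, degree_preserved_swap, load_edge_list,
                      random_deletion, write_edge_list)


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadEdgeList:
    def test_evidence_filter_and_cleanup(self, tmp_path):
        # duplicate rows collapse (max evidence), self-loops dropped
        p = _write(tmp_path, "A\tB\t5\nB\tA\t5\nB\tC\t1\nC\tC\t9\n")
        g = load_edge_list(p, min_evidence=3)
        assert set(g.edges) == {("A", "B")}
        g1 = load_edge_list(p, min_evidence=1)
        assert set(g1.edges) == {("A", "B"), ("B", "C")}

    def test_empty_file(self, tmp_path):
        g = load_edge_list(_write(tmp_path, ""))
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_comments_and_malformed_lines(self, tmp_path):
        g = load_edge_list(_write(tmp_path, "# header\nA\tB\n"))
        assert g.n_edges == 1
        with pytest.raises(EdgeListParseError, match=":2:"):
            load_edge_list(_write(tmp_path, "A\tB\nonlyonecolumn\n"))
        with pytest.raises(EdgeListParseError):
            load_edge_list(_write(tmp_path, "A\tB\tnotanint\n"))

    def test_min_evidence_requires_column(self, tmp_path):
        with pytest.raises(ConfigurationError):
            load_edge_list(_write(tmp_path, "A\tB\nB\tC\n"), min_evidence=3)

    def test_round_trip(self, tmp_path):
        p = _write(tmp_path, "A\tB\t5\nB\tC\t2\nD\tA\t1\n")
        g = load_edge_list(p)
        out = tmp_path / "out.tsv"
        write_edge_list(g, out)
        g2 = load_edge_list(out)
        assert set(g2.edges) == set(g.edges)
        assert g2.evidence == g.evidence


class TestDegreePreservedSwap:
    def test_zero_swaps_identity(self, path4):
        g2, rejected = degree_preserved_swap(path4, 0, seed=1)
        assert set(g2.edges) == set(path4.edges) and rejected == 0

    def test_complete_graph_swaps_always_rejected(self, k4):
        # in K4 every candidate edge already exists, so no swap is possible
        g2, rejected = degree_preserved_swap(k4, 1, seed=3)
        assert set(g2.edges) == set(k4.edges)
        assert rejected > 0

    def test_c4_swaps_keep_graph_simple_and_degrees(self, c4):
        # opposite-edge pairings on a 4-cycle either duplicate a cycle edge
        # (rejected) or rewire onto the chords; degrees never change
        for seed in range(5):
            g2, _rej = degree_preserved_swap(c4, 1, seed=seed)
            assert np.array_equal(g2.degree_sequence(), c4.degree_sequence())
            assert g2.n_edges == c4.n_edges

    def test_degree_sequence_preserved(self):
        import networkx as nx

        er = nx.gnp_random_graph(50, 0.1, seed=7)
        g = Interactome.from_edges([(f"n{a}", f"n{b}") for a, b in er.edges()],
                                   nodes=[f"n{i}" for i in range(50)])
        g2, _rej = degree_preserved_swap(g, 500, seed=11)
        assert np.array_equal(g2.degree_sequence(), g.degree_sequence())
        assert set(g2.edges) != set(g.edges)

    def test_negative_count_rejected(self, c4):
        with pytest.raises(ValueError):
            degree_preserved_swap(c4, -1, seed=0)


class TestRandomDeletion:
    def test_fraction_zero_identity(self, c4):
        g2 = random_deletion(c4, 0.0, "edge", seed=0)
        assert set(g2.edges) == set(c4.edges)

    def test_delete_all_edges_keeps_nodes(self, c4):
        g2 = random_deletion(c4, 1.0, "edge", seed=0)
        assert g2.n_edges == 0 and g2.nodes == c4.nodes

    def test_node_deletion_drops_incident_edges(self):
        tri = Interactome.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        g2 = random_deletion(tri, 1 / 3, "node", seed=5)
        assert g2.n_nodes == 2 and g2.n_edges == 1

    def test_invalid_fraction(self, c4):
        with pytest.raises(ValueError):
            random_deletion(c4, 1.5, "edge", seed=0)


class TestComplementSample:
    def test_forced_single_non_edge(self):
        g = Interactome.from_edges([("A", "B"), ("B", "C")])
        assert complement_sample(g, 1, seed=0) == [("A", "C")]

    def test_complete_graph_capacity_error(self, k4):
        with pytest.raises(CapacityError) as exc:
            complement_sample(k4, 1, seed=0)
        assert exc.value.eligible == 0

    def test_determinism_and_disjointness(self):
        import networkx as nx

        er = nx.gnp_random_graph(20, 0.2, seed=3)
        g = Interactome.from_edges([(f"n{a:02d}", f"n{b:02d}") for a, b in er.edges()],
                                   nodes=[f"n{i:02d}" for i in range(20)])
        s1 = complement_sample(g, 30, seed=9)
        s2 = complement_sample(g, 30, seed=9)
        s3 = complement_sample(g, 30, seed=10)
        assert s1 == s2
        assert s1 != s3
        assert len(set(s1)) == 30
        assert not set(s1) & set(g.edges)

    def test_exclusions_respected(self):
        g = Interactome.from_edges([("A", "B")], nodes=["A", "B", "C"])
        got = complement_sample(g, 1, seed=0, exclude=[("C", "A")])
        assert got == [("B", "C")]


def test_four_cycle_count_on_known_graphs(c4, k4):
    assert count_four_cycles(c4) == 1
    assert count_four_cycles(k4) == 3


def test_canonical_pair_ordering():
    assert canonical_pair("Z", "A") == ("A", "Z") == canonical_pair("A", "Z")
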