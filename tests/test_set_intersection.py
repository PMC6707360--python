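"""Set-intersection graphs: construction, compression, MMCE-SI, MSIGR."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kpclique.core import build_graph
from kpclique.enumeration import mmce
from kpclique.constructions import complete_multipartite
from kpclique.set_intersection import (
    EmptySubsetError,
    NotRecognizedError,
    NotSIInputError,
    build_si_graph,
    compress,
    enumerate_maximal_bicliques,
    make_set_system,
    mmce_si,
    msigr,
    random_set_system,
    read_sets,
    recover_sets,
    write_sets,
)


def clique_sets(stream):
    return {c.members for c in stream}


class TestBuildSiGraph:
    def test_worked_example_adjacency(self, ontology_graph):
        g = ontology_graph
        # element d lies in all of part 2's subsets and none of part 3's
        assert sorted(g.neighbors("d")) == ["{a,b,d}", "{a,d,e}", "{c,d}"]
        assert not g.has_edge("{c,d}", "{b,e}")  # disjoint subsets
        assert g.has_edge("{a,b,d}", "{b,e}")  # share b

    def test_single_element_duplicates_make_complete_graph(self):
        sys = make_set_system("a", [[("s2_1", "a"), ("s2_2", "a")], [("s3_1", "a"), ("s3_2", "a")]])
        g = build_si_graph(sys)
        assert g == complete_multipartite([1, 2, 2]) or g.edge_count() == 8

    def test_empty_subset_rejected(self):
        with pytest.raises(EmptySubsetError):
            make_set_system("ab", [[("s", "")]])


class TestCompression:
    def test_worked_example_sizes_and_edges(self, ontology_system):
        b = compress(ontology_system)
        assert b.graph.k == 2
        assert len(b.graph.parts[1]) == 5  # singleton side
        assert len(b.graph.parts[2]) == 5  # fused subset side
        # edges = sum of subset cardinalities 3+3+2+2+2
        assert b.graph.edge_count() == 12

    def test_singleton_neighborhoods_preserved(self, ontology_system, ontology_graph):
        b = compress(ontology_system)
        for e in ontology_system.universe:
            # identical neighborhood in original and compressed graphs
            assert b.graph.neighbors(e) == ontology_graph.neighbors(e)
            # degree equals the number of subsets containing e
            contained = sum(
                1
                for part in range(2, ontology_system.k + 1)
                for _, members in ontology_system.family(part)
                if e in members
            )
            assert len(b.graph.neighbors(e)) == contained

    @pytest.mark.parametrize("seed", range(8))
    def test_singleton_degree_matches_membership_count(self, seed):
        sys = random_set_system(seed, k=4, n_elements=5)
        b = compress(sys)
        for e in sys.universe:
            contained = sum(
                1
                for part in range(2, sys.k + 1)
                for _, members in sys.family(part)
                if e in members
            )
            assert len(b.graph.neighbors(e)) == contained

    def test_graph_input_goes_through_recognition(self, ontology_graph):
        b = compress(ontology_graph)
        assert b.graph.k == 2

    def test_unrecognizable_graph_rejected(self, five_cycle_tripartite):
        with pytest.raises(NotSIInputError):
            compress(five_cycle_tripartite)


class TestMaximalBicliques:
    def test_worked_example_bicliques(self, ontology_system):
        b = compress(ontology_system)
        found = set(enumerate_maximal_bicliques(b))
        assert frozenset({"b", "{a,b,d}", "{b,e}", "{b,c}"}) in found
        assert frozenset({"b", "c", "{b,c}"}) in found

    def test_complete_bipartite_single_biclique(self):
        sys = make_set_system("ab", [[("s1", "ab"), ("s2", "ab"), ("s3", "ab")]])
        b = compress(sys)
        assert list(enumerate_maximal_bicliques(b)) == [
            frozenset({"a", "b", "s1", "s2", "s3"})
        ]

    def test_one_sided_cliques_suppressed(self, ontology_system):
        b = compress(ontology_system)
        for bic in enumerate_maximal_bicliques(b):
            sides = {b.graph.part_of_label(v) for v in bic}
            assert sides == {1, 2}


class TestMmceSi:
    def test_worked_example_output(self, ontology_system, ontology_graph):
        got = clique_sets(mmce_si(ontology_system))
        assert frozenset({"b", "{a,b,d}", "{b,e}", "{b,c}"}) in got
        # the b/c/{b,c} maximal biclique leaves part 2 unrepresented
        assert frozenset({"b", "c", "{b,c}"}) not in got
        assert got == clique_sets(mmce(ontology_graph))

    @pytest.mark.parametrize("k", [3, 4])
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_direct_enumeration(self, k, seed):
        sys = random_set_system(seed, k=k, n_elements=6)
        g = build_si_graph(sys)
        assert clique_sets(mmce_si(sys)) == clique_sets(mmce(g))

    @pytest.mark.parametrize("seed", range(10))
    def test_clique_count_bounded_by_biclique_count(self, seed):
        sys = random_set_system(seed, k=3, n_elements=6)
        n_cliques = sum(1 for _ in mmce_si(sys))
        n_bicliques = sum(1 for _ in enumerate_maximal_bicliques(compress(sys)))
        assert n_cliques <= n_bicliques


class TestMsigr:
    def test_worked_example_accepts_singleton_part(self, ontology_graph):
        assert msigr(ontology_graph) == 1

    def test_complete_multipartite_accepted(self):
        assert msigr(complete_multipartite([2, 3, 2])) == 1

    def test_five_cycle_rejected(self, five_cycle_tripartite):
        assert msigr(five_cycle_tripartite) is None

    def test_isolated_outside_vertex_rejected(self):
        # vertex with empty neighborhood in every candidate part cannot
        # represent a nonempty subset
        g = build_graph([["a"], ["s"], ["t"]], [("a", "s")])
        assert msigr(g) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_generated_si_graphs_accepted(self, seed):
        sys = random_set_system(seed, k=3, n_elements=5)
        assert msigr(build_si_graph(sys)) is not None


class TestRecoverSets:
    def test_worked_example_subsets_recovered(self, ontology_graph):
        rec = recover_sets(ontology_graph, 1)
        assert set(rec.universe) == set("abcde")
        fam2 = {members for _, members in rec.family(2)}
        assert fam2 == {frozenset("abd"), frozenset("ade"), frozenset("cd")}
        fam3 = {members for _, members in rec.family(3)}
        assert fam3 == {frozenset("be"), frozenset("bc")}

    def test_complete_multipartite_full_universe(self):
        g = complete_multipartite([2, 2, 2])
        rec = recover_sets(g, 1)
        for part in (2, 3):
            for _, members in rec.family(part):
                assert members == frozenset(g.parts[1])

    def test_rejected_part_raises(self, five_cycle_tripartite):
        with pytest.raises(NotRecognizedError):
            recover_sets(five_cycle_tripartite, 1)

    @pytest.mark.parametrize("k", [3, 4])
    @pytest.mark.parametrize("seed", range(10))
    def test_roundtrip_through_graph(self, k, seed):
        sys = random_set_system(seed, k=k, n_elements=5)
        g = build_si_graph(sys)
        part = msigr(g)
        assert part is not None
        rec = recover_sets(g, part)
        assert build_si_graph(rec) == g


class TestSetsFormat:
    def test_roundtrip(self, ontology_system):
        buf = io.StringIO()
        write_sets(ontology_system, buf)
        back = read_sets(io.StringIO(buf.getvalue()))
        assert back.universe == ontology_system.universe
        for part in range(2, 4):
            assert [m for _, m in back.family(part)] == [
                m for _, m in ontology_system.family(part)
            ]

    def test_comments_and_structure(self):
        text = "sets 1\nuniverse a b c # three elements\npart 2 s=a,b t=c\n"
        sys = read_sets(io.StringIO(text))
        assert sys.k == 2
        assert dict(sys.family(2)) == {"s": frozenset("ab"), "t": frozenset("c")}

    @given(seed=st.integers(0, 500))
    def test_random_system_roundtrip(self, seed):
        sys = random_set_system(seed, k=3, n_elements=4)
        buf = io.StringIO()
        write_sets(sys, buf)
        back = read_sets(io.StringIO(buf.getvalue()))
        assert build_si_graph(back) == build_si_graph(sys)
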