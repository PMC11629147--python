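"""Query-graph compilation, overlap semantics, and the brute-force oracle."""

import random

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import URIRef

from omigraph import (
    QueryEdge,
    QueryGraph,
    QueryNode,
    Region,
    Strand,
    TripleStore,
    ValidationError,
    brute_force_overlap,
    compile as compile_query,
    count_distinct,
)
from omigraph.fixtures import load_located_features, random_located_features
from omigraph.query_builder import run
from omigraph.schema_core import local_id_of


def sparql_overlap_pairs(store, mode, strand_policy):
    q = QueryGraph(
        [QueryNode("a", "A"), QueryNode("b", "B")],
        [QueryEdge("a", "b", "overlap", overlap_mode=mode, strand_policy=strand_policy)],
    )
    rows = run(store, q).rows
    return {(local_id_of(URIRef(r["a"])), local_id_of(URIRef(r["b"]))) for r in rows}


class TestOverlapSemantics:
    """Closed 1-based intervals: a single shared base is an overlap."""

    @pytest.mark.parametrize(
        "b_interval,expect",
        [((150, 300), True), ((200, 300), True), ((201, 300), False)],
    )
    def test_boundary_cases(self, b_interval, expect):
        a = [("a0", Region("chr1", 100, 200))]
        b = [("b0", Region("chr1", *b_interval))]
        assert bool(brute_force_overlap(a, b)) is expect
        # and the SPARQL path agrees
        store = TripleStore()
        load_located_features(store, "A", a)
        load_located_features(store, "B", b)
        assert bool(sparql_overlap_pairs(store, "any_overlap", "ignore")) is expect

    def test_disjoint_references_never_overlap(self):
        a = [("a0", Region("chr1", 1, 1000))]
        b = [("b0", Region("chr2", 1, 1000))]
        assert brute_force_overlap(a, b) == set()

    def test_identical_features_self_pair(self):
        f = [("x", Region("chr1", 10, 20, Strand.FORWARD))]
        assert brute_force_overlap(f, f) == {("x", "x")}

    def test_containment_modes(self):
        a = [("a0", Region("chr1", 120, 180))]
        b = [("b0", Region("chr1", 100, 200))]
        assert brute_force_overlap(a, b, "a_within_b") == {("a0", "b0")}
        assert brute_force_overlap(a, b, "b_within_a") == set()

    def test_same_strand_excludes_unknown(self):
        a = [("a0", Region("chr1", 1, 10, Strand.UNKNOWN))]
        b = [("b0", Region("chr1", 5, 15, Strand.UNKNOWN))]
        assert brute_force_overlap(a, b, strand_policy="same_strand") == set()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_any_overlap_symmetry(self, seed):
        rng = random.Random(seed)
        fa = random_located_features(rng, "a", 30)
        fb = random_located_features(rng, "b", 30)
        forward = brute_force_overlap(fa, fb, "any_overlap", "ignore")
        backward = brute_force_overlap(fb, fa, "any_overlap", "ignore")
        assert forward == {(x, y) for y, x in backward}

    def test_sparql_equals_oracle_randomised(self):
        rng = random.Random(42)
        store = TripleStore()
        fa = random_located_features(rng, "A", 40)
        fb = random_located_features(rng, "B", 40)
        load_located_features(store, "A", fa)
        load_located_features(store, "B", fb)
        for mode in ("any_overlap", "a_within_b", "b_within_a"):
            for strand in ("ignore", "same_strand"):
                assert sparql_overlap_pairs(store, mode, strand) == \
                    brute_force_overlap(fa, fb, mode, strand), (mode, strand)


class TestCompileValidation:
    def test_unknown_class(self, fixture_store):
        q = QueryGraph([QueryNode("x", "NoSuchClass")])
        with pytest.raises(ValidationError, match="NoSuchClass"):
            compile_query(q, fixture_store.merged_schema())

    def test_unknown_property(self, fixture_store):
        q = QueryGraph([QueryNode("g", "gene", [("no_such", "=", 1)])])
        with pytest.raises(ValidationError, match="no_such"):
            compile_query(q, fixture_store.merged_schema())

    def test_undeclared_relation(self, fixture_store):
        q = QueryGraph(
            [QueryNode("g", "gene"), QueryNode("c", "Contrast")],
            [QueryEdge("g", "c", "relation", "bogus_relation")],
        )
        with pytest.raises(ValidationError, match="bogus_relation"):
            compile_query(q, fixture_store.merged_schema())

    def test_overlap_requires_located_classes(self, fixture_store):
        q = QueryGraph(
            [QueryNode("g", "gene"), QueryNode("c", "Contrast")],
            [QueryEdge("g", "c", "overlap")],
        )
        with pytest.raises(ValidationError, match="not a located class"):
            compile_query(q, fixture_store.merged_schema())

    def test_disconnected_graph_rejected(self):
        q = QueryGraph([QueryNode("a", "gene"), QueryNode("b", "gene")])
        with pytest.raises(ValidationError, match="disconnected"):
            q.validate_structure()

    def test_single_node_select_compiles(self, fixture_store):
        sparql = compile_query(QueryGraph([QueryNode("g", "gene")]),
                               fixture_store.merged_schema())
        assert sparql.startswith("SELECT DISTINCT ?g")
        assert "ORDER BY ?g" in sparql


class TestCounting:
    def test_empty_store_counts_zero(self):
        store = TripleStore()
        load_located_features(store, "A", [])
        assert count_distinct(store, QueryGraph([QueryNode("a", "A")]), "a") == 0

    def test_monotonicity_filters_and_edges_never_increase(self, fixture_store):
        base = QueryGraph(
            [QueryNode("deg", "DEG"), QueryNode("contrast", "Contrast")],
            [QueryEdge("deg", "contrast", "relation", "differentiallyExpressedIn")],
        )
        filtered = QueryGraph(
            [QueryNode("deg", "DEG", [("regulation_sense", "=", "UP")]),
             QueryNode("contrast", "Contrast", [("label", "=", "4Qvs4W")])],
            base.edges,
        )
        extended = QueryGraph(
            base.nodes + [QueryNode("peak", "ATACpeak"), QueryNode("gene", "gene")],
            base.edges + [QueryEdge("deg", "gene", "relation", "gene"),
                          QueryEdge("gene", "peak", "overlap")],
        )
        n_base = count_distinct(fixture_store, base, "deg")
        assert count_distinct(fixture_store, filtered, "deg") <= n_base
        assert count_distinct(fixture_store, extended, "deg") <= n_base

    def test_numeric_filter(self, fixture_store, fixture_study):
        # up-regulation is encoded as a positive log2 fold-change, so the
        # numeric filter must recover exactly the planted UP counts
        _, truth = fixture_study
        up = QueryGraph([QueryNode("deg", "DEG", [("log2_fold_change", ">", 0)])])
        everything = QueryGraph([QueryNode("deg", "DEG")])
        n_up = count_distinct(fixture_store, up, "deg")
        n_all = count_distinct(fixture_store, everything, "deg")
        expected_up = sum(v for k, v in truth.expected.items()
                          if k.startswith("deg_") and k.endswith("_UP"))
        assert n_up == expected_up
        assert n_all > n_up


class TestSerialisation:
    def test_round_trip(self):
        q = QueryGraph(
            [QueryNode("gene", "gene", [("Name", "=", "MYH7")], ["Name"]),
             QueryNode("dmr", "DMR", selected=["methylation_sense"])],
            [QueryEdge("dmr", "gene", "relation", "associated_gene")],
        )
        assert QueryGraph.from_dict(q.to_dict()).to_dict() == q.to_dict()

    def test_overlap_edge_round_trip(self):
        q = QueryGraph(
            [QueryNode("a", "gene"), QueryNode("b", "ATACpeak")],
            [QueryEdge("a", "b", "overlap", overlap_mode="a_within_b",
                       strand_policy="same_strand")],
        )
        restored = QueryGraph.from_dict(q.to_dict())
        assert restored.edges[0].overlap_mode == "a_within_b"
        assert restored.edges[0].strand_policy == "same_strand"
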