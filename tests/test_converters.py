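"""Header classification, table/GFF3 lifting, design graphs, link inference."""

import io
import random

import pytest
from rdflib import RDF, Literal, URIRef

from omigraph import (
    ConversionError,
    DesignTables,
    TripleStore,
    ValidationError,
    classify_header,
    convert_gff3,
    convert_table,
    infer_links,
    read_table,
)
from omigraph.converters import build_design_graph, parse_gff3
from omigraph.schema_core import FALDO, mint_entity_uri, mint_property_uri

NS = "https://ex.org"


class TestClassifyHeader:
    def test_relation_and_attribute_columns(self):
        roles = classify_header(["DEG", "differentiallyExpressedIn@Contrast", "FDR"])
        assert [r.role for r in roles] == ["entity_id", "relation", "attribute"]
        assert roles[1].relation_label == "differentiallyExpressedIn"
        assert roles[1].target_class == "Contrast"

    def test_position_columns(self):
        roles = classify_header(["DMR", "chromosome", "start", "end", "strand"])
        assert [r.role for r in roles] == [
            "entity_id", "position_reference", "position_start",
            "position_end", "position_strand",
        ]

    @pytest.mark.parametrize("header,role", [
        ("Chrom", "position_reference"), ("REF", "position_reference"),
        ("Begin", "position_start"), ("STOP", "position_end"),
    ])
    def test_position_synonyms_case_insensitive(self, header, role):
        assert classify_header(["x", header])[1].role == role

    def test_single_column_table(self):
        assert [r.role for r in classify_header(["X"])] == ["entity_id"]

    def test_duplicate_headers_rejected(self):
        with pytest.raises(ValidationError, match=r"\['FDR'\]"):
            classify_header(["DEG", "FDR", "FDR"])

    def test_relation_split_at_last_at(self):
        role = classify_header(["x", "a@b@Contrast"])[1]
        assert role.relation_label == "a@b"
        assert role.target_class == "Contrast"


def _table(text):
    return read_table(io.StringIO(text))


class TestConvertTable:
    def test_one_entity_per_row_with_relation(self):
        table = _table(
            "DEG,differentiallyExpressedIn@Contrast,FDR\n"
            "d1,HCMvsControl,0.01\nd2,HCMvsControl,0.002\nd3,HCMvsControl,0.3\n"
        )
        batch, schema = convert_table(table, NS)
        entities = {s for s, p, o in batch.triples if p == RDF.type}
        assert len(entities) == 3
        contrast = mint_entity_uri(NS, "Contrast", "HCMvsControl")
        links = [t for t in batch.triples
                 if t[1] == mint_property_uri(NS, "differentiallyExpressedIn")]
        assert len(links) == 3 and all(o == contrast for _, _, o in links)

    def test_shared_entity_id_merges(self):
        table = _table("gene,annotation\ng1,caste\ng1,longevity\n")
        batch, _ = convert_table(table, NS)
        entities = {s for s, p, o in batch.triples if p == RDF.type}
        assert len(entities) == 1
        values = {o for s, p, o in batch.triples
                  if p == mint_property_uri(NS, "annotation")}
        assert values == {Literal("caste"), Literal("longevity")}

    def test_entity_count_equals_distinct_ids(self):
        rng = random.Random(0)
        ids = [f"e{rng.randrange(40)}" for _ in range(100)]
        text = "thing,score\n" + "".join(f"{i},{n}\n" for n, i in enumerate(ids))
        batch, _ = convert_table(_table(text), NS)
        entities = {s for s, p, o in batch.triples if p == RDF.type}
        assert len(entities) == len(set(ids))  # brute-force distinct count

    def test_numeric_column_typing(self):
        table = _table("x,count,ratio,name\na,1,0.5,foo\nb,2,1.5,bar\n")
        batch, schema = convert_table(table, NS)
        by_label = {p.label: p.range for p in schema[0].properties}
        assert by_label["count"] == "integer"
        assert by_label["ratio"] == "decimal"
        assert by_label["name"] == "string"

    def test_missing_cells_emit_no_triple(self):
        table = _table("x,note\na,\nb,hello\n")
        batch, _ = convert_table(table, NS)
        notes = [t for t in batch.triples if t[1] == mint_property_uri(NS, "note")]
        assert len(notes) == 1

    def test_multivalued_relation_cells_split_on_comma(self):
        table = _table('x,member@group\na,"g1,g2"\n')
        batch, _ = convert_table(table, NS)
        targets = {o for s, p, o in batch.triples if p == mint_property_uri(NS, "member")}
        assert targets == {mint_entity_uri(NS, "group", "g1"), mint_entity_uri(NS, "group", "g2")}

    def test_inverted_interval_row_skipped(self, caplog):
        table = _table("peak,chromosome,start,end\np1,chr1,100,200\np2,chr1,300,250\n")
        with caplog.at_level("WARNING"):
            batch, _ = convert_table(table, NS)
        entities = {s for s, p, o in batch.triples
                    if p == RDF.type and str(o).startswith(NS)}
        assert len(entities) == 1
        assert "skipped" in caplog.text

    def test_empty_entity_id_rejected(self):
        table = _table("x,y\n,1\n")
        with pytest.raises(ConversionError, match="line 2"):
            convert_table(table, NS)

    def test_schema_soundness(self):
        """Every data predicate is declared in the returned schema."""
        table = _table(
            "DMR,chromosome,start,end,associated_gene@gene,methylation_sense\n"
            "m1,chr1,10,20,g1,hyper\n"
        )
        batch, schema = convert_table(table, NS)
        declared = {mint_property_uri(NS, p.label) for p in schema[0].properties}
        from rdflib import RDFS
        for s, p, o in batch.triples:
            if str(p).startswith(f"{NS}/property/"):
                assert p in declared, p
            else:
                assert p in (RDF.type, RDFS.label) or str(p).startswith(str(FALDO))


TOY_GFF = """##gff-version 3
chr1\ttoy\tgene\t100\t900\t.\t+\t.\tID=g1;Name=GENE1
chr1\ttoy\tmRNA\t100\t900\t.\t+\t.\tID=t1;Parent=g1
chr1\ttoy\texon\t100\t400\t.\t+\t.\tID=e1;Parent=t1
"""


class TestConvertGff3:
    def test_toy_hierarchy(self):
        batch, schema = convert_gff3(TOY_GFF, NS)
        entities = {s for s, p, o in batch.triples if p == RDF.type
                    and str(o).startswith(NS)}
        assert len(entities) == 3
        parents = [t for t in batch.triples if t[1] == mint_property_uri(NS, "parent")]
        assert len(parents) == 2
        locations = [t for t in batch.triples if t[1] == FALDO.location]
        assert len(locations) == 3
        assert {c.label for c in schema} == {"gene", "mRNA", "exon"}

    def test_multi_parent(self):
        gff = TOY_GFF + "chr1\ttoy\tmRNA\t100\t900\t.\t+\t.\tID=t2;Parent=g1,g2\n"
        batch, _ = convert_gff3(gff, NS)
        t2 = mint_entity_uri(NS, "mRNA", "t2")
        parents = [o for s, p, o in batch.triples
                   if s == t2 and p == mint_property_uri(NS, "parent")]
        assert len(parents) == 2

    def test_empty_file_is_schema_only(self):
        batch, schema = convert_gff3("##gff-version 3\n", NS)
        assert len(batch) == 0 and schema == []

    def test_unparseable_line_reports_line_number(self):
        with pytest.raises(ConversionError, match="line 2"):
            convert_gff3("##gff-version 3\nchr1\tbroken\n", NS)

    def test_missing_id_gets_deterministic_synthetic_id(self):
        gff = "##gff-version 3\nchr1\ttoy\tgene\t5\t50\t.\t-\t.\tName=x\n"
        batch1, _ = convert_gff3(gff, NS)
        batch2, _ = convert_gff3(gff, NS)
        assert batch1.triples == batch2.triples
        subjects = {str(s) for s, p, o in batch1.triples if p == RDF.type and str(o).startswith(NS)}
        assert any("gene%3Achr1%3A5-50" in s for s in subjects)

    def test_percent_escapes_decoded(self):
        recs = parse_gff3("chr1\ttoy\tgene\t1\t10\t.\t+\t.\tID=g1;Name=a%2Cb\n")
        assert recs[0].attributes["Name"] == "a,b"

    def test_whitelist_filters_types(self):
        gff = TOY_GFF + "chr1\ttoy\tregion\t1\t1000\t.\t+\t.\tID=r1\n"
        batch, schema = convert_gff3(gff, NS)
        assert "region" not in {c.label for c in schema}


class TestDesignGraph:
    def _bee_design(self):
        return DesignTables(
            conditions=[(c, {}) for c in ("2Q", "2W", "4Q", "4W")],
            contexts=[(c, [c]) for c in ("2Q", "2W", "4Q", "4W")],
            contrasts=[("2Qvs2W", "2Q", "2W"), ("4Qvs4W", "4Q", "4W")],
        )

    def test_entity_counts(self):
        batch = build_design_graph(self._bee_design(), NS)
        entities = {s for s, p, o in batch.triples if p == RDF.type}
        assert len(entities) == 4 + 4 + 2

    def test_membership_triples(self):
        design = DesignTables(
            conditions=[("a", {}), ("b", {})],
            contexts=[("ab", ["a", "b"])],
            contrasts=[],
        )
        batch = build_design_graph(design, NS)
        members = [t for t in batch.triples if t[1] == mint_property_uri(NS, "condition")]
        assert len(members) == 2

    def test_empty_design(self):
        assert len(build_design_graph(DesignTables(), NS)) == 0

    def test_undeclared_context_rejected(self):
        design = DesignTables(conditions=[("a", {})], contexts=[("a", ["a"])],
                              contrasts=[("avsb", "a", "b")])
        with pytest.raises(ValidationError, match="undeclared context 'b'"):
            build_design_graph(design, NS)


class TestInferLinks:
    def test_relation_link(self, fixture_store):
        schema = fixture_store.merged_schema()
        links = infer_links(schema)
        assert ("DEG", "relation", "Contrast") in links

    def test_location_links_between_located_classes(self, fixture_store):
        links = infer_links(fixture_store.merged_schema())
        location_pairs = {frozenset((a, b)) for a, k, b in links if k == "location"}
        assert frozenset(("gene", "ATACpeak")) in location_pairs

    def test_unlinked_class(self):
        from omigraph.schema_core import EntityClassDef, mint_class_uri

        schema = [EntityClassDef("Reference", mint_class_uri(NS, "Reference"))]
        assert infer_links(schema) == []

    def test_unresolved_relation_reported_not_fatal(self):
        from omigraph.schema_core import EntityClassDef, PropertyDef, mint_class_uri

        schema = [EntityClassDef("A", mint_class_uri(NS, "A"), False,
                                 [PropertyDef("to", "relation", "Missing")])]
        assert ("A", "unresolved-relation", "Missing") in infer_links(schema)


class TestConservationInvariants:
    def test_double_load_is_idempotent(self, fixture_study):
        path, _ = fixture_study
        store = TripleStore()
        from omigraph.fixtures import integrate_fixture_dir

        integrate_fixture_dir(store, path)
        count = store.triple_count
        integrate_fixture_dir(store, path)
        assert store.triple_count == count

    def test_gff_entity_conservation(self, fixture_study):
        path, truth = fixture_study
        with open(f"{path}/genes.gff3") as fh:
            batch, _ = convert_gff3(fh.read(), "https://check.org")
        entities = {s for s, p, o in batch.triples
                    if p == RDF.type and str(o).startswith("https://check.org")}
        assert len(entities) == truth.feature_count
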