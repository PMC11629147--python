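"""URI minting, Region/FALDO serialisation and dataset-schema triples."""

from urllib.parse import quote

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import RDF, RDFS, URIRef

from omigraph import Region, Strand, ValidationError
from omigraph.schema_core import (
    FALDO,
    EntityClassDef,
    PropertyDef,
    merge_schemas,
    mint_class_uri,
    mint_entity_uri,
    region_from_triples,
    region_triples,
    schema_triples,
)

NS = "https://ex.org"


class TestMinting:
    @pytest.mark.parametrize(
        "cls,local,expected",
        [
            ("gene", "MYH7", "https://ex.org/gene/MYH7"),
            # percent-encoding per RFC 3986 (oracle: urllib.parse.quote)
            ("gene", "a b/c", "https://ex.org/gene/" + quote("a b/c", safe="")),
            ("DEG", "id:with:colons", "https://ex.org/DEG/" + quote("id:with:colons", safe="")),
        ],
    )
    def test_examples(self, cls, local, expected):
        assert str(mint_entity_uri(NS, cls, local)) == expected

    def test_deterministic(self):
        minted = {mint_entity_uri(NS, "gene", "BRCA2") for _ in range(1000)}
        assert len(minted) == 1

    def test_empty_local_id_rejected(self):
        with pytest.raises(ValidationError, match="empty identifier"):
            mint_entity_uri(NS, "gene", "")


class TestRegion:
    def test_inverted_interval_rejected(self):
        with pytest.raises(ValidationError, match="start 200 > end 100"):
            Region("chr1", 200, 100)

    def test_positions_start_at_one(self):
        with pytest.raises(ValidationError):
            Region("chr1", 0, 10)

    def test_single_base_region(self):
        r = Region("chr1", 5, 5)
        batch = region_triples(URIRef(f"{NS}/x/1"), r, NS)
        positions = [int(o) for s, p, o in batch.triples if p == FALDO.position]
        assert positions == [5, 5]

    def test_stranded_triple_count_hand_enumerated(self):
        # 1 location + 1 region type + begin/end links (2)
        # + per position node: ExactPosition + strand class + position + reference (4 x 2)
        # + chromosome label + 4 flat attributes = 17
        batch = region_triples(URIRef(f"{NS}/g/1"), Region("chr1", 100, 200, Strand.FORWARD), NS)
        assert len(batch) == 17

    def test_unknown_strand_has_no_strand_position_class(self):
        batch = region_triples(URIRef(f"{NS}/g/1"), Region("chr1", 100, 200), NS)
        types = {o for s, p, o in batch.triples if p == RDF.type}
        assert FALDO.ForwardStrandPosition not in types
        assert FALDO.ReverseStrandPosition not in types
        assert len(batch) == 15

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        reference=st.text(alphabet="chrXY_12345", min_size=1, max_size=8),
        start=st.integers(min_value=1, max_value=10**8),
        length=st.integers(min_value=0, max_value=10**6),
        strand=st.sampled_from(list(Strand)),
    )
    def test_roundtrip(self, reference, start, length, strand):
        """Region -> FALDO triples -> parse-back is exact."""
        region = Region(reference, start, start + length, strand)
        subject = URIRef(f"{NS}/feat/1")
        batch = region_triples(subject, region, NS)
        assert region_from_triples(batch.triples, subject) == region


class TestSchemaTriples:
    def test_one_class_declarations(self):
        deg = EntityClassDef(
            "DEG",
            mint_class_uri(NS, "DEG"),
            False,
            [
                PropertyDef("FDR", "attribute", "decimal"),
                PropertyDef("differentiallyExpressedIn", "relation", "Contrast"),
            ],
        )
        batch = schema_triples([deg], NS)
        class_decls = [(s, o) for s, p, o in batch.triples if p == RDF.type and o == RDFS.Class]
        prop_decls = [(s, o) for s, p, o in batch.triples if p == RDF.type and o == RDF.Property]
        domains = {o for s, p, o in batch.triples if p == RDFS.domain}
        assert len(class_decls) == 1
        assert len(prop_decls) == 2
        assert domains == {deg.uri}

    def test_located_class_links_to_region_abstraction(self):
        gene = EntityClassDef("gene", mint_class_uri(NS, "gene"), True, [])
        batch = schema_triples([gene], NS)
        assert any(o == FALDO.Region for _, _, o in batch.triples)

    def test_empty_class_list(self):
        assert len(schema_triples([], NS)) == 0

    def test_duplicate_labels_rejected(self):
        gene = EntityClassDef("gene", mint_class_uri(NS, "gene"))
        with pytest.raises(ValidationError, match="duplicate"):
            schema_triples([gene, gene], NS)

    def test_merge_is_set_union(self):
        a = [
            EntityClassDef(
                "gene", mint_class_uri(NS, "gene"), True,
                [PropertyDef("Name", "attribute", "string")],
            )
        ]
        b = [
            EntityClassDef(
                "gene", mint_class_uri(NS, "gene"), True,
                [PropertyDef("Name", "attribute", "string"),
                 PropertyDef("biotype", "attribute", "string")],
            )
        ]
        merged = merge_schemas([a, b])
        assert len(merged) == 1
        assert merged[0].property_labels() == {"Name", "biotype"}
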