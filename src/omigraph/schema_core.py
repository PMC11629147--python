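"""Core vocabulary of the integration schema.

The integration model is organised in five blocks — genomic features,
functional annotation, experimental design (Condition / Context / Contrast),
differential result entities (DEGs, DMRs, ...) and located regulation
entities (peaks, compartment switches, binding sites) — all glued together
by two mechanisms:

* shared, deterministically minted URIs, so that two datasets mentioning
  the same gene produce one merged node, and
* FALDO locations, so that any two located entities can be joined on
  genomic overlap without an explicit foreign key.

Every located entity is serialised twice: once as a FALDO region (begin /
end position nodes typed by strand, ``faldo:reference`` to a chromosome
entity) and once as four flat attribute triples (``reference``, ``start``,
``end``, ``strand``).  The FALDO form is the interoperable one; the flat
form keeps attribute filters and interval arithmetic cheap in SPARQL.

Coordinates are 1-based inclusive throughout (the GFF3 and FALDO
convention); an interval of a single base has ``start == end``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union
from urllib.parse import quote, unquote

from rdflib import Literal, Namespace, RDF, RDFS, URIRef, XSD

from .errors import ValidationError

FALDO = Namespace("http://biohackathon.org/resource/faldo#")

#: Default project namespace; override per project via config.
DEFAULT_NAMESPACE = "https://omigraph.org/data"

#: Attribute labels reserved for the flat positional encoding.
POSITION_LABELS = ("reference", "start", "end", "strand")

#: Literal range names accepted for attribute properties.
ATTRIBUTE_RANGES = ("string", "integer", "decimal")

_XSD_RANGE = {"string": XSD.string, "integer": XSD.integer, "decimal": XSD.decimal}


class Strand(enum.Enum):
    FORWARD = "+"
    REVERSE = "-"
    UNKNOWN = "."

    @classmethod
    def from_gff(cls, symbol: str) -> "Strand":
        try:
            return cls(symbol)
        except ValueError:
            raise ValidationError(
                f"unsupported strand symbol {symbol!r}: expected '+', '-' or '.'"
            ) from None


@dataclass(frozen=True)
class Region:
    """A located genomic interval, 1-based inclusive on both ends."""

    reference: str
    start: int
    end: int
    strand: Strand = Strand.UNKNOWN

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValidationError("region has an empty reference name")
        if self.start < 1:
            raise ValidationError(f"region start {self.start} < 1 on {self.reference}")
        if self.start > self.end:
            raise ValidationError(
                f"region start {self.start} > end {self.end} on {self.reference}"
            )

    def overlaps(self, other: "Region") -> bool:
        """Closed-interval intersection test (a shared single base counts)."""
        return (
            self.reference == other.reference
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "Region") -> bool:
        return (
            self.reference == other.reference
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class PropertyDef:
    """One column of a dataset schema: a literal attribute or a relation.

    ``range`` names a literal type (string/integer/decimal) for attributes
    and an entity class label for relations.
    """

    label: str
    kind: str  # "attribute" | "relation"
    range: str

    def __post_init__(self) -> None:
        if self.kind not in ("attribute", "relation"):
            raise ValidationError(f"property {self.label!r}: unknown kind {self.kind!r}")
        if self.kind == "attribute" and self.range not in ATTRIBUTE_RANGES:
            raise ValidationError(
                f"attribute {self.label!r}: range must be one of {ATTRIBUTE_RANGES}"
            )


@dataclass
class EntityClassDef:
    label: str
    uri: URIRef
    is_located: bool = False
    properties: list[PropertyDef] = field(default_factory=list)

    def property_labels(self) -> set[str]:
        return {p.label for p in self.properties}

    def get_property(self, label: str) -> Optional[PropertyDef]:
        for p in self.properties:
            if p.label == label:
                return p
        return None


@dataclass
class TripleBatch:
    """A set of triples destined for one named graph."""

    graph_name: URIRef
    triples: set = field(default_factory=set)

    def add(self, s: URIRef, p: URIRef, o) -> None:
        self.triples.add((s, p, o))

    def extend(self, other: "TripleBatch") -> None:
        self.triples |= other.triples

    def __len__(self) -> int:
        return len(self.triples)


# ---------------------------------------------------------------------------
# URI minting


def _encode(part: str) -> str:
    return quote(part, safe="")


def mint_entity_uri(namespace: str, class_label: str, local_id: str) -> URIRef:
    """Mint the URI of one entity: ``<namespace>/<class>/<pct-encoded id>``.

    Minting is deterministic, so two datasets mentioning the same
    (class, id) pair produce the same node and merge on load.
    """
    if not class_label:
        raise ValidationError("cannot mint a URI for an empty class label")
    if not local_id:
        raise ValidationError(
            f"cannot mint a URI in class {class_label!r} for an empty identifier"
        )
    return URIRef(f"{namespace.rstrip('/')}/{_encode(class_label)}/{_encode(local_id)}")


def mint_class_uri(namespace: str, class_label: str) -> URIRef:
    if not class_label:
        raise ValidationError("cannot mint a URI for an empty class label")
    return URIRef(f"{namespace.rstrip('/')}/{_encode(class_label)}")


def mint_property_uri(namespace: str, label: str) -> URIRef:
    """Property URIs live under a shared ``property/`` path so that the same
    column name used by two tables yields one predicate."""
    if not label:
        raise ValidationError("cannot mint a URI for an empty property label")
    return URIRef(f"{namespace.rstrip('/')}/property/{_encode(label)}")


def local_id_of(uri: URIRef) -> str:
    """Inverse of :func:`mint_entity_uri` for the local identifier part."""
    return unquote(str(uri).rsplit("/", 1)[-1])


def _schema_ns(namespace: str) -> Namespace:
    return Namespace(namespace.rstrip("/") + "/schema/")


# ---------------------------------------------------------------------------
# FALDO serialisation

_STRAND_POSITION_CLASS = {
    Strand.FORWARD: FALDO.ForwardStrandPosition,
    Strand.REVERSE: FALDO.ReverseStrandPosition,
}


def region_triples(
    subject: URIRef,
    region: Region,
    namespace: str = DEFAULT_NAMESPACE,
    graph_name: Optional[URIRef] = None,
) -> TripleBatch:
    """Serialise one entity's location as FALDO plus flat attributes.

    Emits a ``faldo:location`` region node whose begin/end are
    ``faldo:ExactPosition`` nodes (additionally typed Forward/Reverse
    StrandPosition when the strand is known) carrying ``faldo:position``
    and ``faldo:reference``, and four plain attribute triples so the same
    location is filterable without walking the FALDO nodes.
    """
    batch = TripleBatch(graph_name or URIRef(f"{subject}/location-graph"))
    region_node = URIRef(f"{subject}/region")
    begin_node = URIRef(f"{subject}/region/begin")
    end_node = URIRef(f"{subject}/region/end")
    chrom = mint_entity_uri(namespace, "reference", region.reference)

    batch.add(subject, FALDO.location, region_node)
    batch.add(region_node, RDF.type, FALDO.Region)
    batch.add(region_node, FALDO.begin, begin_node)
    batch.add(region_node, FALDO.end, end_node)
    for node, pos in ((begin_node, region.start), (end_node, region.end)):
        batch.add(node, RDF.type, FALDO.ExactPosition)
        strand_class = _STRAND_POSITION_CLASS.get(region.strand)
        if strand_class is not None:
            batch.add(node, RDF.type, strand_class)
        batch.add(node, FALDO.position, Literal(pos, datatype=XSD.integer))
        batch.add(node, FALDO.reference, chrom)
    batch.add(chrom, RDFS.label, Literal(region.reference))

    prop = lambda label: mint_property_uri(namespace, label)  # noqa: E731
    batch.add(subject, prop("reference"), Literal(region.reference))
    batch.add(subject, prop("start"), Literal(region.start, datatype=XSD.integer))
    batch.add(subject, prop("end"), Literal(region.end, datatype=XSD.integer))
    batch.add(subject, prop("strand"), Literal(region.strand.value))
    return batch


def region_from_triples(
    triples: Iterable[tuple], subject: URIRef
) -> Optional[Region]:
    """Recover a :class:`Region` from the FALDO triples of ``subject``.

    Returns None when the subject carries no ``faldo:location``.  Used by
    round-trip tests and by consumers that only see the RDF form.
    """
    index: dict[tuple, list] = {}
    for s, p, o in triples:
        index.setdefault((s, p), []).append(o)

    regions = index.get((subject, FALDO.location))
    if not regions:
        return None
    region_node = regions[0]
    (begin,) = index[(region_node, FALDO.begin)]
    (end,) = index[(region_node, FALDO.end)]
    (start_lit,) = index[(begin, FALDO.position)]
    (end_lit,) = index[(end, FALDO.position)]
    (chrom,) = index[(begin, FALDO.reference)]
    (chrom_label,) = index[(chrom, RDFS.label)]
    types = set(index.get((begin, RDF.type), []))
    if FALDO.ForwardStrandPosition in types:
        strand = Strand.FORWARD
    elif FALDO.ReverseStrandPosition in types:
        strand = Strand.REVERSE
    else:
        strand = Strand.UNKNOWN
    return Region(str(chrom_label), int(start_lit), int(end_lit), strand)


# ---------------------------------------------------------------------------
# Dataset schema triples


def schema_triples(
    classes: list[EntityClassDef],
    namespace: str = DEFAULT_NAMESPACE,
    graph_name: Optional[URIRef] = None,
) -> TripleBatch:
    """Self-describing RDFS triples for a dataset schema.

    Declares each entity class, each property with its kind / domain /
    range, and links located classes to the abstract FALDO Region so a
    query layer can discover which classes support positional joins.
    """
    labels = [c.label for c in classes]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValidationError(f"duplicate class labels in schema: {sorted(dupes)}")

    ns = _schema_ns(namespace)
    batch = TripleBatch(graph_name or URIRef(ns["dataset-schema"]))
    for cdef in classes:
        batch.add(cdef.uri, RDF.type, RDFS.Class)
        batch.add(cdef.uri, RDFS.label, Literal(cdef.label))
        if cdef.is_located:
            batch.add(cdef.uri, ns["locatedOn"], FALDO.Region)
        for p in cdef.properties:
            puri = mint_property_uri(namespace, p.label)
            batch.add(puri, RDF.type, RDF.Property)
            batch.add(puri, RDFS.label, Literal(p.label))
            batch.add(puri, RDFS.domain, cdef.uri)
            batch.add(puri, ns["kind"], Literal(p.kind))
            if p.kind == "attribute":
                batch.add(puri, RDFS.range, _XSD_RANGE[p.range])
            else:
                batch.add(puri, RDFS.range, mint_class_uri(namespace, p.range))
    return batch


def merge_schemas(
    schemas: Iterable[list[EntityClassDef]],
) -> list[EntityClassDef]:
    """Union dataset schemas by class label; properties unioned by label.

    When two datasets disagree on a property's range the first wins — the
    open-world reading is that later datasets refine, never retract.
    """
    merged: dict[str, EntityClassDef] = {}
    for schema in schemas:
        for cdef in schema:
            if cdef.label not in merged:
                merged[cdef.label] = EntityClassDef(
                    cdef.label, cdef.uri, cdef.is_located, list(cdef.properties)
                )
            else:
                tgt = merged[cdef.label]
                tgt.is_located = tgt.is_located or cdef.is_located
                known = tgt.property_labels()
                for p in cdef.properties:
                    if p.label not in known:
                        tgt.properties.append(p)
                        known.add(p.label)
    return list(merged.values())


def check_relation_ranges(classes: list[EntityClassDef]) -> list[str]:
    """Lazy range validation: report relation targets that no dataset
    declares.  Unresolved targets are warnings, not errors — a relation may
    point at a class integrated later."""
    known = {c.label for c in classes}
    problems = []
    for cdef in classes:
        for p in cdef.properties:
            if p.kind == "relation" and p.range not in known:
                problems.append(
                    f"{cdef.label}.{p.label} targets undeclared class {p.range!r}"
                )
    return problems
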