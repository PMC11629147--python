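"""Lift GFF3 annotations, omics result tables and design tables to RDF.

Tabular convention (AskOmics-style): the first column holds the entity
identifier and its header names the entity class — so a results table whose
first column is headed ``gene`` *enriches* the gene entities created from
the genome annotation rather than creating a parallel class.  A header of
the form ``label@TargetClass`` declares a relation column whose cells are
identifiers in the target class; any of ``chromosome``/``start``/``end``/
``strand`` (and common synonyms) declare the positional columns that make
the class located; everything else is a literal attribute.

Cross-links between datasets are therefore detected two ways: by relation
columns, and implicitly between any two located classes through their FALDO
regions.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union
from urllib.parse import unquote

from rdflib import Literal, RDF, RDFS, URIRef, XSD

from .errors import ConversionError, ValidationError
from .schema_core import (
    EntityClassDef,
    PropertyDef,
    Region,
    Strand,
    TripleBatch,
    mint_class_uri,
    mint_entity_uri,
    mint_property_uri,
    region_triples,
)

log = logging.getLogger(__name__)

_REFERENCE_HEADERS = {"chromosome", "chrom", "chr", "ref", "reference", "seqid"}
_START_HEADERS = {"start", "begin"}
_END_HEADERS = {"end", "stop"}
_STRAND_HEADERS = {"strand"}

#: GFF3 feature types retained by default, in addition to any *RNA type
#: present in the file (ncRNA, lncRNA, miRNA, tRNA...).
DEFAULT_FEATURE_TYPES = frozenset(
    {"gene", "mRNA", "transcript", "exon", "CDS", "five_prime_UTR", "three_prime_UTR"}
)


@dataclass(frozen=True)
class ColumnRole:
    source_header: str
    role: str  # entity_id | attribute | relation | position_reference | ...
    relation_label: Optional[str] = None
    target_class: Optional[str] = None


@dataclass
class TabularDataset:
    """A parsed table: entity class (first header), column roles, rows."""

    entity_class: str
    columns: list[ColumnRole]
    rows: list[list[str]]

    def __post_init__(self) -> None:
        ncol = len(self.columns)
        for i, row in enumerate(self.rows):
            if len(row) != ncol:
                raise ValidationError(
                    f"table {self.entity_class!r} row {i + 1}: "
                    f"{len(row)} cells for {ncol} columns"
                )
        roles = {c.role for c in self.columns}
        pos = roles & {"position_reference", "position_start", "position_end"}
        if pos and len(pos) != 3:
            raise ValidationError(
                f"table {self.entity_class!r}: positional columns are all-or-none "
                f"(reference/start/end), found only {sorted(pos)}"
            )

    @property
    def is_located(self) -> bool:
        return any(c.role == "position_start" for c in self.columns)


def classify_header(headers: list[str]) -> list[ColumnRole]:
    """Assign a role to every column of a table from its header alone.

    The first column is always the entity identifier; ``label@Target``
    headers are relations (split at the last ``@``); chromosome / start /
    end / strand synonyms become positional columns; the rest are
    attributes.
    """
    if not headers:
        raise ValidationError("empty header list")
    dupes = sorted({h for h in headers if headers.count(h) > 1})
    if dupes:
        raise ValidationError(f"duplicate column headers: {dupes}")

    roles = [ColumnRole(headers[0], "entity_id")]
    for h in headers[1:]:
        low = h.strip().lower()
        if "@" in h:
            label, _, target = h.rpartition("@")
            if not label or not target:
                raise ValidationError(
                    f"malformed relation header {h!r}: expected 'label@TargetClass'"
                )
            roles.append(ColumnRole(h, "relation", label, target))
        elif low in _REFERENCE_HEADERS:
            roles.append(ColumnRole(h, "position_reference"))
        elif low in _START_HEADERS:
            roles.append(ColumnRole(h, "position_start"))
        elif low in _END_HEADERS:
            roles.append(ColumnRole(h, "position_end"))
        elif low in _STRAND_HEADERS:
            roles.append(ColumnRole(h, "position_strand"))
        else:
            roles.append(ColumnRole(h, "attribute"))
    return roles


def read_table(
    source: Union[str, TextIO],
    entity_class: Optional[str] = None,
    delimiter: Optional[str] = None,
) -> TabularDataset:
    """Read a CSV/TSV file (header row required) into a TabularDataset.

    The delimiter is sniffed from the header line unless given.  The entity
    class defaults to the first column's header.
    """
    if isinstance(source, str):
        with open(source, newline="") as fh:
            return read_table(fh, entity_class, delimiter)
    text = source.read()
    if not text.strip():
        raise ConversionError("empty table: no header row")
    if delimiter is None:
        header_line = text.splitlines()[0]
        delimiter = "\t" if header_line.count("\t") >= header_line.count(",") and "\t" in header_line else ","
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    headers = [h.strip() for h in rows[0]]
    columns = classify_header(headers)
    body = [r for r in rows[1:] if any(cell.strip() for cell in r)]
    return TabularDataset(entity_class or headers[0], columns, body)


def _column_is_numeric(cells: list[str]) -> Optional[str]:
    """Return 'integer'/'decimal' when every non-empty cell parses, else None."""
    seen = False
    integral = True
    for c in cells:
        c = c.strip()
        if not c:
            continue
        seen = True
        try:
            float(c)
        except ValueError:
            return None
        if integral:
            try:
                int(c)
            except ValueError:
                integral = False
    if not seen:
        return None
    return "integer" if integral else "decimal"


def _typed_literal(cell: str, range_name: str) -> Literal:
    if range_name == "integer":
        return Literal(int(cell), datatype=XSD.integer)
    if range_name == "decimal":
        return Literal(float(cell), datatype=XSD.double)
    return Literal(cell)


def convert_table(
    table: TabularDataset,
    namespace: str,
    graph_name: Optional[URIRef] = None,
) -> tuple[TripleBatch, list[EntityClassDef]]:
    """One entity per row; attributes as typed literals, relations as object
    triples, positions as FALDO regions.

    Rows sharing an identifier merge into one entity (set semantics).  Rows
    whose interval is inverted (start > end) are skipped with a warning; an
    empty identifier is an error naming the row.
    """
    cls = table.entity_class
    class_uri = mint_class_uri(namespace, cls)
    graph_name = graph_name or URIRef(f"{namespace.rstrip('/')}/graph/{cls}")
    batch = TripleBatch(graph_name)

    col_cells = list(zip(*table.rows)) if table.rows else [[] for _ in table.columns]
    props: list[PropertyDef] = [PropertyDef("label", "attribute", "string")]
    ranges: dict[int, str] = {}
    for i, col in enumerate(table.columns):
        if col.role == "attribute":
            num = _column_is_numeric(list(col_cells[i])) if table.rows else None
            ranges[i] = num or "string"
            props.append(PropertyDef(col.source_header, "attribute", ranges[i]))
        elif col.role == "relation":
            props.append(PropertyDef(col.relation_label, "relation", col.target_class))
    if table.is_located:
        props += [
            PropertyDef("reference", "attribute", "string"),
            PropertyDef("start", "attribute", "integer"),
            PropertyDef("end", "attribute", "integer"),
            PropertyDef("strand", "attribute", "string"),
        ]

    idx = {c.role: i for i, c in enumerate(table.columns) if c.role.startswith("position")}
    skipped = 0
    for rownum, row in enumerate(table.rows, start=2):
        entity_id = row[0].strip()
        if not entity_id:
            raise ConversionError(
                f"table {cls!r} line {rownum}: empty entity identifier"
            )
        region = None
        if table.is_located:
            ref = row[idx["position_reference"]].strip()
            start_c = row[idx["position_start"]].strip()
            end_c = row[idx["position_end"]].strip()
            strand_c = (
                row[idx["position_strand"]].strip()
                if "position_strand" in idx
                else "."
            )
            if ref and start_c and end_c:
                try:
                    region = Region(
                        ref, int(float(start_c)), int(float(end_c)),
                        Strand.from_gff(strand_c or "."),
                    )
                except ValidationError as exc:
                    log.warning("table %r line %d skipped: %s", cls, rownum, exc)
                    skipped += 1
                    continue

        subject = mint_entity_uri(namespace, cls, entity_id)
        batch.add(subject, RDF.type, class_uri)
        batch.add(subject, RDFS.label, Literal(entity_id))
        for i, col in enumerate(table.columns):
            cell = row[i].strip()
            if not cell or col.role == "entity_id" or col.role.startswith("position"):
                continue
            if col.role == "attribute":
                batch.add(
                    subject,
                    mint_property_uri(namespace, col.source_header),
                    _typed_literal(cell, ranges[i]),
                )
            elif col.role == "relation":
                pred = mint_property_uri(namespace, col.relation_label)
                for target_id in (v.strip() for v in cell.split(",")):
                    if target_id:
                        batch.add(
                            subject,
                            pred,
                            mint_entity_uri(namespace, col.target_class, target_id),
                        )
        if region is not None:
            batch.extend(region_triples(subject, region, namespace, graph_name))

    if skipped:
        log.warning("table %r: %d rows skipped (invalid intervals)", cls, skipped)
    schema = [EntityClassDef(cls, class_uri, table.is_located, props)]
    return batch, schema


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffRecord:
    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]
    parents: list[str] = field(default_factory=list)

    @property
    def feature_id(self) -> Optional[str]:
        return self.attributes.get("ID")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[unquote(key).strip()] = unquote(value).strip()
    return attrs


def parse_gff3(stream: Union[str, TextIO, Iterable[str]]) -> list[GffRecord]:
    """Parse GFF3 lines into records (header/comment lines skipped, parsing
    stops at an embedded ``##FASTA`` block).  Percent-escapes in attribute
    keys and values are decoded; ``Parent`` lists are split on commas."""
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    records = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if line.startswith("##FASTA"):
            break
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ConversionError(
                f"GFF3 line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        seqid, source, ftype, start_s, end_s, score, strand, phase, attr_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ConversionError(
                f"GFF3 line {lineno}: non-integer coordinates {start_s!r}..{end_s!r}"
            ) from None
        if start > end:
            raise ConversionError(f"GFF3 line {lineno}: start {start} > end {end}")
        attrs = _parse_gff_attributes(attr_s)
        parents = [p for p in attrs.get("Parent", "").split(",") if p]
        records.append(
            GffRecord(seqid, source, ftype, start, end, score, strand, phase, attrs, parents)
        )
    return records


def _default_whitelist(records: list[GffRecord]) -> set[str]:
    present = {r.type for r in records}
    rna_like = {t for t in present if t.endswith("RNA") or t.endswith("_RNA")}
    return set(DEFAULT_FEATURE_TYPES) | rna_like


_GFF_ATTRIBUTE_KEYS = ("Name", "biotype", "gene_type", "gene_biotype", "description")


def convert_gff3(
    gff3: Union[str, TextIO, Iterable[str]],
    namespace: str,
    feature_whitelist: Optional[set[str]] = None,
    graph_name: Optional[URIRef] = None,
    type_aliases: Optional[dict[str, str]] = None,
) -> tuple[TripleBatch, list[EntityClassDef]]:
    """Convert a GFF3 annotation into entities classed by feature type.

    Each retained record becomes an entity of its (possibly aliased) GFF
    type with a FALDO region; ``Parent`` attributes become ``parent``
    relation triples (one per listed parent, forward references allowed);
    ``Name`` and biotype-ish attributes become literal attributes.
    Records without an ID get the deterministic synthetic identifier
    ``<type>:<seqid>:<start>-<end>:<ordinal>``.
    """
    records = parse_gff3(gff3)
    whitelist = feature_whitelist if feature_whitelist is not None else _default_whitelist(records)
    aliases = type_aliases or {}
    retained = [r for r in records if r.type in whitelist]

    graph_name = graph_name or URIRef(f"{namespace.rstrip('/')}/graph/annotation")
    batch = TripleBatch(graph_name)

    # first pass: identifier + class per record, so Parent targets resolve
    # to the right class even on forward references
    id_to_class: dict[str, str] = {}
    assigned: list[tuple[GffRecord, str, str]] = []
    synth_ordinal = 0
    for rec in retained:
        cls = aliases.get(rec.type, rec.type)
        fid = rec.feature_id
        if not fid:
            synth_ordinal += 1
            fid = f"{rec.type}:{rec.seqid}:{rec.start}-{rec.end}:{synth_ordinal}"
        id_to_class.setdefault(fid, cls)
        assigned.append((rec, fid, cls))

    classes: dict[str, EntityClassDef] = {}
    parent_pred = mint_property_uri(namespace, "parent")
    unresolved: set[str] = set()
    for rec, fid, cls in assigned:
        if cls not in classes:
            classes[cls] = EntityClassDef(
                cls,
                mint_class_uri(namespace, cls),
                True,
                [
                    PropertyDef("label", "attribute", "string"),
                    PropertyDef("reference", "attribute", "string"),
                    PropertyDef("start", "attribute", "integer"),
                    PropertyDef("end", "attribute", "integer"),
                    PropertyDef("strand", "attribute", "string"),
                ],
            )
        cdef = classes[cls]
        subject = mint_entity_uri(namespace, cls, fid)
        batch.add(subject, RDF.type, cdef.uri)
        batch.add(subject, RDFS.label, Literal(fid))
        for key in _GFF_ATTRIBUTE_KEYS:
            if key in rec.attributes:
                batch.add(
                    subject,
                    mint_property_uri(namespace, key),
                    Literal(rec.attributes[key]),
                )
                if cdef.get_property(key) is None:
                    cdef.properties.append(PropertyDef(key, "attribute", "string"))
        for parent_id in rec.parents:
            target_cls = id_to_class.get(parent_id)
            if target_cls is None:
                unresolved.add(parent_id)
                target_cls = "feature"
            batch.add(subject, parent_pred, mint_entity_uri(namespace, target_cls, parent_id))
            if cdef.get_property("parent") is None:
                cdef.properties.append(PropertyDef("parent", "relation", target_cls))
        region = Region(rec.seqid, rec.start, rec.end, Strand.from_gff(rec.strand or "."))
        batch.extend(region_triples(subject, region, namespace, graph_name))

    if unresolved:
        log.warning(
            "GFF3: %d Parent identifiers never declared by a retained record: %s",
            len(unresolved),
            ", ".join(sorted(unresolved)[:5]),
        )
    return batch, list(classes.values())


# ---------------------------------------------------------------------------
# Experimental design


@dataclass
class DesignTables:
    """Condition / Context / Contrast declarations of an experimental plan.

    Conditions are atomic experimental conditions; a Context groups one or
    more Conditions; a Contrast compares two Contexts (A vs B) and is the
    entity differential results point at.
    """

    conditions: list[tuple[str, dict[str, str]]] = field(default_factory=list)
    contexts: list[tuple[str, list[str]]] = field(default_factory=list)
    contrasts: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        cond_ids = {c for c, _ in self.conditions}
        ctx_ids = {c for c, _ in self.contexts}
        for ctx, members in self.contexts:
            missing = [m for m in members if m not in cond_ids]
            if missing:
                raise ValidationError(
                    f"context {ctx!r} references undeclared conditions {missing}"
                )
        for contrast, a, b in self.contrasts:
            for ref in (a, b):
                if ref not in ctx_ids:
                    raise ValidationError(
                        f"contrast {contrast!r} references undeclared context {ref!r}"
                    )


def design_schema(namespace: str) -> list[EntityClassDef]:
    label = PropertyDef("label", "attribute", "string")
    return [
        EntityClassDef("Condition", mint_class_uri(namespace, "Condition"), False, [label]),
        EntityClassDef(
            "Context",
            mint_class_uri(namespace, "Context"),
            False,
            [label, PropertyDef("condition", "relation", "Condition")],
        ),
        EntityClassDef(
            "Contrast",
            mint_class_uri(namespace, "Contrast"),
            False,
            [
                label,
                PropertyDef("context_A", "relation", "Context"),
                PropertyDef("context_B", "relation", "Context"),
            ],
        ),
    ]


def build_design_graph(
    design: DesignTables,
    namespace: str,
    graph_name: Optional[URIRef] = None,
) -> TripleBatch:
    """Serialise the experimental plan block."""
    design.validate()
    graph_name = graph_name or URIRef(f"{namespace.rstrip('/')}/graph/design")
    batch = TripleBatch(graph_name)

    def declare(cls: str, local_id: str) -> URIRef:
        uri = mint_entity_uri(namespace, cls, local_id)
        batch.add(uri, RDF.type, mint_class_uri(namespace, cls))
        batch.add(uri, RDFS.label, Literal(local_id))
        return uri

    for cond_id, attrs in design.conditions:
        uri = declare("Condition", cond_id)
        for key, value in attrs.items():
            if value:
                batch.add(uri, mint_property_uri(namespace, key), Literal(value))
    member_pred = mint_property_uri(namespace, "condition")
    for ctx_id, members in design.contexts:
        uri = declare("Context", ctx_id)
        for m in members:
            batch.add(uri, member_pred, mint_entity_uri(namespace, "Condition", m))
    pred_a = mint_property_uri(namespace, "context_A")
    pred_b = mint_property_uri(namespace, "context_B")
    for contrast_id, a, b in design.contrasts:
        uri = declare("Contrast", contrast_id)
        batch.add(uri, pred_a, mint_entity_uri(namespace, "Context", a))
        batch.add(uri, pred_b, mint_entity_uri(namespace, "Context", b))
    return batch


def read_design_dir(path: str) -> DesignTables:
    """Load conditions.csv / contexts.csv / contrasts.csv from a directory.

    contexts.csv and contrasts.csv use relation columns (``condition@Condition``,
    ``context_A@Context``...), with multi-valued cells comma-separated.
    """
    import os

    def cell(table: TabularDataset, row: list[str], label: str) -> str:
        for i, col in enumerate(table.columns):
            if col.source_header == label or col.relation_label == label:
                return row[i].strip()
        raise ValidationError(f"design table {table.entity_class!r}: missing column {label!r}")

    conditions_t = read_table(os.path.join(path, "conditions.csv"))
    contexts_t = read_table(os.path.join(path, "contexts.csv"))
    contrasts_t = read_table(os.path.join(path, "contrasts.csv"))
    conditions = []
    attr_cols = [c for c in conditions_t.columns if c.role == "attribute"]
    for row in conditions_t.rows:
        attrs = {c.source_header: cell(conditions_t, row, c.source_header) for c in attr_cols}
        conditions.append((row[0].strip(), attrs))
    contexts = [
        (row[0].strip(), [m.strip() for m in cell(contexts_t, row, "condition").split(",") if m.strip()])
        for row in contexts_t.rows
    ]
    contrasts = [
        (row[0].strip(), cell(contrasts_t, row, "context_A"), cell(contrasts_t, row, "context_B"))
        for row in contrasts_t.rows
    ]
    return DesignTables(conditions, contexts, contrasts)


# ---------------------------------------------------------------------------
# Cross-link inference


def infer_links(
    schemas: list[EntityClassDef],
) -> list[tuple[str, str, str]]:
    """Detect cross-dataset links: declared relations plus implicit
    location links between every pair of located classes.

    Returns (source class, kind ∈ {relation, location, unresolved-relation},
    target class) tuples; an unresolved relation target is reported, not
    fatal.
    """
    if not schemas:
        raise ValidationError("infer_links needs at least one schema")
    known = {c.label for c in schemas}
    links: list[tuple[str, str, str]] = []
    for cdef in schemas:
        for p in cdef.properties:
            if p.kind == "relation":
                kind = "relation" if p.range in known else "unresolved-relation"
                links.append((cdef.label, kind, p.range))
    located = sorted(c.label for c in schemas if c.is_located)
    for i, a in enumerate(located):
        for b in located[i + 1 :]:
            links.append((a, "location", b))
    return links
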