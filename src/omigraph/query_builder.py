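"""Compile abstract query graphs into SPARQL.

A :class:`QueryGraph` is the programmatic analogue of building a query by
walking the integrated schema: nodes are typed entity variables carrying
attribute filters, edges are either declared relations (``DEG
--differentiallyExpressedIn--> Contrast``) or genomic-overlap constraints
between two located classes.  Compilation validates the graph against the
merged dataset schema, then emits a SPARQL 1.1 SELECT whose overlap edges
are interval inequalities over the flat positional attributes (closed,
1-based intervals: two regions sharing a single base DO overlap).

:func:`brute_force_overlap` re-implements the exact same overlap semantics
by all-pairs enumeration in Python and serves as the independent oracle
the SPARQL path is tested against.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdflib import RDFS, URIRef

from .errors import ValidationError
from .schema_core import (
    DEFAULT_NAMESPACE,
    EntityClassDef,
    Region,
    Strand,
    mint_class_uri,
    mint_property_uri,
)

COMPARATORS = {"=", "!=", "<", "<=", ">", ">=", "contains"}
OVERLAP_MODES = ("any_overlap", "a_within_b", "b_within_a")
STRAND_POLICIES = ("ignore", "same_strand")

_VAR_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _safe(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


@dataclass
class QueryNode:
    var: str
    entity_class: str
    filters: list[tuple[str, str, object]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not _VAR_RE.match(self.var):
            raise ValidationError(f"invalid variable name {self.var!r}")
        for prop, cmp, _ in self.filters:
            if cmp not in COMPARATORS:
                raise ValidationError(
                    f"node {self.var}: unknown comparator {cmp!r} on {prop!r}"
                )


@dataclass
class QueryEdge:
    from_var: str
    to_var: str
    kind: str  # "relation" | "overlap"
    relation_label: Optional[str] = None
    overlap_mode: str = "any_overlap"
    strand_policy: str = "ignore"

    def __post_init__(self) -> None:
        if self.kind not in ("relation", "overlap"):
            raise ValidationError(f"unknown edge kind {self.kind!r}")
        if self.kind == "relation" and not self.relation_label:
            raise ValidationError("relation edge needs a relation_label")
        if self.overlap_mode not in OVERLAP_MODES:
            raise ValidationError(f"unknown overlap mode {self.overlap_mode!r}")
        if self.strand_policy not in STRAND_POLICIES:
            raise ValidationError(f"unknown strand policy {self.strand_policy!r}")


@dataclass
class QueryGraph:
    nodes: list[QueryNode]
    edges: list[QueryEdge] = field(default_factory=list)
    aggregate: Optional[tuple[str, str]] = None  # ("count_distinct", var)

    def node(self, var: str) -> QueryNode:
        for n in self.nodes:
            if n.var == var:
                return n
        raise ValidationError(f"no query node named {var!r}")

    def validate_structure(self) -> None:
        if not self.nodes:
            raise ValidationError("a query graph needs at least one node")
        names = [n.var for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate node variables: {names}")
        for e in self.edges:
            self.node(e.from_var), self.node(e.to_var)
        # connectivity
        adjacency: dict[str, set[str]] = {n.var: set() for n in self.nodes}
        for e in self.edges:
            adjacency[e.from_var].add(e.to_var)
            adjacency[e.to_var].add(e.from_var)
        seen = {names[0]}
        frontier = [names[0]]
        while frontier:
            for nxt in adjacency[frontier.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        if seen != set(names):
            raise ValidationError(
                f"query graph is disconnected: unreachable nodes {sorted(set(names) - seen)}"
            )
        if self.aggregate is not None:
            op, var = self.aggregate
            if op != "count_distinct":
                raise ValidationError(f"unsupported aggregate {op!r}")
            self.node(var)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "var": n.var,
                    "class": n.entity_class,
                    "filters": [list(f) for f in n.filters],
                    "selected": list(n.selected),
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "from": e.from_var,
                    "to": e.to_var,
                    "kind": e.kind,
                    **({"relation": e.relation_label} if e.kind == "relation" else {}),
                    **(
                        {"mode": e.overlap_mode, "strand": e.strand_policy}
                        if e.kind == "overlap"
                        else {}
                    ),
                }
                for e in self.edges
            ],
            **(
                {"aggregate": {"op": self.aggregate[0], "var": self.aggregate[1]}}
                if self.aggregate
                else {}
            ),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "QueryGraph":
        nodes = [
            QueryNode(
                n["var"],
                n["class"],
                [tuple(f) for f in n.get("filters", [])],
                list(n.get("selected", [])),
            )
            for n in doc.get("nodes", [])
        ]
        edges = [
            QueryEdge(
                e["from"],
                e["to"],
                e["kind"],
                e.get("relation"),
                e.get("mode", "any_overlap"),
                e.get("strand", "ignore"),
            )
            for e in doc.get("edges", [])
        ]
        aggregate = None
        if "aggregate" in doc:
            aggregate = (doc["aggregate"]["op"], doc["aggregate"]["var"])
        q = cls(nodes, edges, aggregate)
        q.validate_structure()
        return q

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# compilation


def _literal_sparql(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    escaped = str(value).replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def _position_patterns(var: str, namespace: str) -> tuple[str, dict[str, str]]:
    """Bind the flat positional attributes of ``var``; returns (pattern,
    binding-variable map with keys ref/start/end/strand)."""
    names = {
        "ref": f"?{var}__ref",
        "start": f"?{var}__start",
        "end": f"?{var}__end",
        "strand": f"?{var}__strand",
    }
    lines = [
        f"?{var} <{mint_property_uri(namespace, 'reference')}> {names['ref']} .",
        f"?{var} <{mint_property_uri(namespace, 'start')}> {names['start']} .",
        f"?{var} <{mint_property_uri(namespace, 'end')}> {names['end']} .",
        f"?{var} <{mint_property_uri(namespace, 'strand')}> {names['strand']} .",
    ]
    return "\n  ".join(lines), names


def overlap_pattern(
    a_var: str,
    b_var: str,
    mode: str = "any_overlap",
    strand_policy: str = "ignore",
    namespace: str = DEFAULT_NAMESPACE,
) -> str:
    """SPARQL fragment constraining two located variables to overlap.

    Same reference is enforced structurally (shared variable); intervals
    are closed and 1-based, so ``any_overlap`` is
    ``start(a) <= end(b) && start(b) <= end(a)``, and containment modes
    tighten both inequalities.  ``same_strand`` additionally requires equal,
    known strands.
    """
    if mode not in OVERLAP_MODES:
        raise ValidationError(f"unknown overlap mode {mode!r}")
    a_pat, a = _position_patterns(a_var, namespace)
    b_pat, b = _position_patterns(b_var, namespace)
    # same chromosome via a shared join variable (cheaper than FILTER =)
    shared = f"?{a_var}__{b_var}__ref"
    a_pat = a_pat.replace(a["ref"], shared)
    b_pat = b_pat.replace(b["ref"], shared)
    if mode == "any_overlap":
        cond = f"{a['start']} <= {b['end']} && {b['start']} <= {a['end']}"
    elif mode == "a_within_b":
        cond = f"{b['start']} <= {a['start']} && {a['end']} <= {b['end']}"
    else:  # b_within_a
        cond = f"{a['start']} <= {b['start']} && {b['end']} <= {a['end']}"
    lines = [a_pat, b_pat, f"FILTER({cond})"]
    if strand_policy == "same_strand":
        lines.append(
            f"FILTER({a['strand']} = {b['strand']} && {a['strand']} != \".\")"
        )
    return "\n  ".join(lines)


def compile(
    q: QueryGraph,
    schema: Sequence[EntityClassDef],
    namespace: str = DEFAULT_NAMESPACE,
) -> str:
    """Compile a validated query graph into a SPARQL 1.1 SELECT string."""
    q.validate_structure()
    by_label = {c.label: c for c in schema}

    def class_of(var: str) -> EntityClassDef:
        cls = q.node(var).entity_class
        if cls not in by_label:
            raise ValidationError(f"unknown entity class {cls!r} (node {var})")
        return by_label[cls]

    patterns: list[str] = []
    projected: list[str] = []
    for node in q.nodes:
        cdef = class_of(node.var)
        patterns.append(f"?{node.var} a <{mint_class_uri(namespace, cdef.label)}> .")
        projected.append(f"?{node.var}")
        needed = {p for p, _, _ in node.filters} | set(node.selected)
        bound: dict[str, str] = {}
        for prop in sorted(needed):
            pdef = cdef.get_property(prop)
            if pdef is None:
                raise ValidationError(
                    f"class {cdef.label!r} declares no property {prop!r} (node {node.var})"
                )
            if pdef.kind != "attribute":
                raise ValidationError(
                    f"{cdef.label}.{prop} is a relation; filter/select needs an attribute"
                )
            v = f"?{node.var}__{_safe(prop)}"
            bound[prop] = v
            # entity identifiers are stored as rdfs:label; everything else
            # under the project property namespace
            pred = RDFS.label if prop == "label" else mint_property_uri(namespace, prop)
            patterns.append(f"?{node.var} <{pred}> {v} .")
        for prop in node.selected:
            projected.append(bound[prop])
        for prop, cmp, value in node.filters:
            v = bound[prop]
            if cmp == "contains":
                patterns.append(f"FILTER(CONTAINS(STR({v}), {_literal_sparql(str(value))}))")
            else:
                op = cmp
                patterns.append(f"FILTER({v} {op} {_literal_sparql(value)})")

    for edge in q.edges:
        if edge.kind == "relation":
            src = class_of(edge.from_var)
            pdef = src.get_property(edge.relation_label)
            if pdef is None or pdef.kind != "relation":
                raise ValidationError(
                    f"class {src.label!r} declares no relation {edge.relation_label!r}"
                )
            pred = mint_property_uri(namespace, edge.relation_label)
            patterns.append(f"?{edge.from_var} <{pred}> ?{edge.to_var} .")
        else:
            for endpoint in (edge.from_var, edge.to_var):
                if not class_of(endpoint).is_located:
                    raise ValidationError(
                        f"overlap edge endpoint {endpoint!r} "
                        f"({class_of(endpoint).label}) is not a located class"
                    )
            patterns.append(
                overlap_pattern(
                    edge.from_var, edge.to_var, edge.overlap_mode,
                    edge.strand_policy, namespace,
                )
            )

    body = "\n  ".join(patterns)
    if q.aggregate is not None:
        _, var = q.aggregate
        return (
            f"SELECT (COUNT(DISTINCT ?{var}) AS ?n)\n"
            f"WHERE {{\n  {body}\n}}"
        )
    head = " ".join(dict.fromkeys(projected))
    return (
        f"SELECT DISTINCT {head}\n"
        f"WHERE {{\n  {body}\n}}\n"
        f"ORDER BY {projected[0]}"
    )


# ---------------------------------------------------------------------------
# execution helpers


def run(store, q: QueryGraph):
    """Compile against the store's merged schema and execute."""
    sparql = compile(q, store.merged_schema(), store.namespace)
    return store.run_select(sparql)


def count_distinct(store, q: QueryGraph, var: str) -> int:
    """Execute ``q`` as a COUNT(DISTINCT ?var) aggregate and return it."""
    q.node(var)
    counted = QueryGraph(q.nodes, q.edges, ("count_distinct", var))
    result = run(store, counted)
    if not result.rows:
        return 0
    return int(result.rows[0].get("n", 0))


# ---------------------------------------------------------------------------
# independent oracle


def _pair_matches(ra: Region, rb: Region, mode: str, strand_policy: str) -> bool:
    if ra.reference != rb.reference:
        return False
    if strand_policy == "same_strand":
        if ra.strand != rb.strand or ra.strand is Strand.UNKNOWN:
            return False
    if mode == "any_overlap":
        return ra.start <= rb.end and rb.start <= ra.end
    if mode == "a_within_b":
        return rb.contains(ra)
    if mode == "b_within_a":
        return ra.contains(rb)
    raise ValidationError(f"unknown overlap mode {mode!r}")


def brute_force_overlap(
    features_a: Iterable[tuple[str, Region]],
    features_b: Iterable[tuple[str, Region]],
    mode: str = "any_overlap",
    strand_policy: str = "ignore",
) -> set[tuple[str, str]]:
    """All-pairs overlap evaluation with the exact semantics of
    :func:`overlap_pattern`; the reference oracle for the SPARQL path."""
    fa, fb = list(features_a), list(features_b)
    return {
        (ida, idb)
        for (ida, ra), (idb, rb) in itertools.product(fa, fb)
        if _pair_matches(ra, rb, mode, strand_policy)
    }
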