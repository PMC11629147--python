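"""Named-graph triple storage and SPARQL execution.

One named graph per integrated file, with the default graph configured as
the union of all named graphs, so queries span datasets freely while any
single dataset can be dropped or exported on its own.  Backed by rdflib's
in-memory engine; the contract (load batches, run SELECT, expose the
merged dataset schema) is small enough that a persistent or remote engine
could stand behind it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from rdflib import Dataset, URIRef

from .errors import StoreError
from .schema_core import EntityClassDef, TripleBatch, merge_schemas, schema_triples


@dataclass
class NamedGraphRef:
    name: URIRef
    triple_count: int
    source: str = ""


@dataclass
class ResultTable:
    variables: list[str]
    rows: list[dict]

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, var: str) -> list:
        return [r.get(var) for r in self.rows]


class TripleStore:
    """In-memory union-default triplestore with per-dataset named graphs."""

    def __init__(self, namespace: Optional[str] = None):
        from .schema_core import DEFAULT_NAMESPACE

        self.namespace = namespace or DEFAULT_NAMESPACE
        self._ds = Dataset(default_union=True)
        self._schemas: list[list[EntityClassDef]] = []
        self._graphs: dict[URIRef, NamedGraphRef] = {}

    # -- loading ------------------------------------------------------------

    def load_graph(
        self,
        batch: TripleBatch,
        schema: Optional[list[EntityClassDef]] = None,
        source: str = "",
    ) -> NamedGraphRef:
        """Load a batch into its named graph (set semantics: reloading an
        identical batch leaves the count unchanged).  When a dataset schema
        is given, its RDFS triples are loaded too and the merged schema is
        extended."""
        if batch is None:
            raise StoreError("cannot load a null batch")
        try:
            g = self._ds.graph(batch.graph_name)
            for t in batch.triples:
                g.add(t)
            if schema:
                sbatch = schema_triples(schema, self.namespace, batch.graph_name)
                for t in sbatch.triples:
                    g.add(t)
                self._schemas.append(schema)
        except Exception as exc:  # pragma: no cover - engine failure
            raise StoreError(f"loading graph {batch.graph_name}: {exc}") from exc
        ref = NamedGraphRef(batch.graph_name, len(g), source)
        self._graphs[batch.graph_name] = ref
        return ref

    def graph_refs(self) -> list[NamedGraphRef]:
        return [
            NamedGraphRef(name, len(self._ds.graph(name)), ref.source)
            for name, ref in self._graphs.items()
        ]

    @property
    def triple_count(self) -> int:
        return sum(len(self._ds.graph(n)) for n in self._graphs)

    # -- querying -----------------------------------------------------------

    def run_select(self, sparql: str) -> ResultTable:
        """Run a SPARQL 1.1 SELECT over the union of all loaded graphs."""
        try:
            result = self._ds.query(sparql)
        except Exception as exc:
            raise StoreError(f"SPARQL error: {exc}") from exc
        variables = [str(v) for v in (result.vars or [])]
        rows = []
        for binding in result:
            row = {}
            for var in variables:
                value = binding[var] if var in binding.labels else None
                if value is not None:
                    row[var] = value.toPython()
            rows.append(row)
        return ResultTable(variables, rows)

    def merged_schema(self) -> list[EntityClassDef]:
        """Union of the dataset schemas of everything loaded so far."""
        return merge_schemas(self._schemas)

    # -- export / reload ----------------------------------------------------

    def export_graph(self, name: URIRef, path: str, fmt: str = "nt") -> None:
        """Serialise one named graph as Turtle (``ttl``) or N-Triples (``nt``)."""
        if name not in self._graphs:
            raise StoreError(f"no such graph: {name}")
        fmt_map = {"nt": "nt", "ttl": "turtle", "turtle": "turtle"}
        if fmt not in fmt_map:
            raise StoreError(f"unsupported export format {fmt!r} (nt, ttl)")
        self._ds.graph(name).serialize(destination=path, format=fmt_map[fmt], encoding="utf-8")

    def import_graph(self, name: URIRef, path: str, fmt: str = "nt", source: str = "") -> NamedGraphRef:
        """Parse a serialised graph back into the named graph ``name``."""
        fmt_map = {"nt": "nt", "ttl": "turtle", "turtle": "turtle"}
        try:
            g = self._ds.graph(name)
            g.parse(path, format=fmt_map[fmt])
        except Exception as exc:
            raise StoreError(f"importing graph {name} from {path}: {exc}") from exc
        ref = NamedGraphRef(name, len(g), source or path)
        self._graphs[name] = ref
        return ref
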