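# Methods

## Data model

The integration schema treats every source file as a set of entities with
three kinds of structure: literal attributes, declared relations, and
genomic location. Entities are identified by deterministic URIs
(`<namespace>/<class>/<percent-encoded id>`, RFC 3986 encoding with an
empty safe set), so integration is a pure union: loading the same file
twice, or two files that mention the same identifier, never creates
duplicate nodes. Each integrated file occupies its own named graph and the
default graph is configured as the union of all named graphs, which is
what lets one query span datasets freely while any single dataset remains
individually exportable or removable.

Alongside the data, every conversion emits a self-describing dataset
schema in RDFS: class declarations, property declarations with kind
(attribute/relation), domain and range, and a marker linking located
classes to the abstract FALDO `Region`. The merged schema drives query
validation — a query graph that filters an undeclared property or walks an
undeclared relation is rejected before any SPARQL is generated. Relation
ranges are validated lazily (a warning, not an error, when the target
class has not been integrated yet), because files arrive in arbitrary
order.

## Coordinates and locations

All coordinates are 1-based and inclusive on both ends, the GFF3 and FALDO
convention; the generated tables use the same convention, so no
half-open/closed conversion happens anywhere in the pipeline. A located
entity is serialised twice:

- a FALDO region: `faldo:location` → region node, `faldo:begin`/`faldo:end`
  → `faldo:ExactPosition` nodes carrying `faldo:position` and
  `faldo:reference` (an entity per chromosome), with strand expressed by
  additionally typing the position nodes `ForwardStrandPosition` /
  `ReverseStrandPosition` (no extra type when the strand is unknown);
- four flat attribute triples (`reference`, `start`, `end`, `strand`).

The FALDO form is the interoperable, standards-facing encoding; the flat
form is what the query compiler uses for overlap joins and attribute
filters, because a FALDO walk costs six extra triple patterns per endpoint
in every query. Both encodings are emitted unconditionally; the round-trip
test recovers the exact `(reference, start, end, strand)` tuple from the
FALDO form alone.

GFF strands `+`/`-`/`.` map to forward/reverse/unknown; numeric BED-style
strands are rejected. Chromosome labels are kept verbatim from each
source; mismatched naming between sources (e.g. `chr1` vs `1`) is the
user's to reconcile before integration, since silent normalisation would
corrupt counts.

## Overlap semantics

Intervals are closed, so two regions sharing exactly one base *do*
overlap: `any_overlap(a,b) ≡ start(a) ≤ end(b) ∧ start(b) ≤ end(a)` on a
shared reference. Containment modes (`a_within_b`, `b_within_a`) tighten
both inequalities; `same_strand` additionally requires equal strands, with
unknown strand never matching. Same-reference is enforced structurally (a
shared SPARQL join variable rather than a FILTER), which keeps the join
intermediate proportional to per-chromosome feature counts.

`brute_force_overlap` re-implements exactly these semantics by all-pairs
enumeration in plain Python. It is deliberately independent of the SPARQL
path — no shared predicate construction, no shared store — and the
acceptance suite asserts set equality of the two answers (which checks
both false positives and false negatives) across 50 random studies, all
three modes and both strand policies.

Overlap joins are FILTER-based at query time; `omigraph
materialize-overlaps` optionally writes precomputed overlap triples for
large graphs where repeated joins dominate. Correctness first, performance
opt-in.

## Tabular and GFF3 conversion

Column roles come from headers alone: first column = entity id and class
name; `label@TargetClass` = relation (split at the *last* `@`);
case-insensitive `chromosome|chrom|chr|ref|reference|seqid`,
`start|begin`, `end|stop`, `strand` = positional columns (all-or-none for
reference/start/end; strand optional); everything else = attribute. A
column is typed numeric iff every non-empty cell parses (integer kept
integral, otherwise double); missing cells emit no triple (open-world),
never an empty-string literal. Relation cells split on commas, mirroring
GFF3 `Parent` lists. Rows with inverted intervals are skipped with a
counted warning; empty identifiers abort with the row number.

GFF3 conversion retains a whitelist of feature types (gene, mRNA,
transcript, exon, CDS, UTRs, plus any `*RNA` type present in the file) and
classes each record by its GFF type — `transcript` and `mRNA` stay
distinct classes unless the caller passes a type-alias map. `Parent`
attributes become `parent` relation triples, one per listed parent, with
forward references resolved by a first pass over the file; parents never
declared are still linked (under a generic `feature` class) with a
warning. Records without an `ID` get the deterministic synthetic
identifier `<type>:<seqid>:<start>-<end>:<ordinal>`.

UP/DOWN and hyper/hypo are plain string attributes (`regulation_sense`,
`methylation_sense`), not subclasses: they arrive as added spreadsheet
columns and should stay filterable like any other column.

## Synthetic study generator

The generator emulates the *shape* of a two-timepoint, two-caste study:
conditions 2Q/2W/4Q/4W, one context per condition, contrasts 2Qvs2W and
4Qvs4W, with more differential and epigenetic signal at day 4 than day 2.
Defaults: 30 genes on 3 chromosomes (25 in the fast test battery), genes
500–3000 bp separated by 500–2000 bp gaps, 6 UP + 5 DOWN DEGs in 2Qvs2W
and 10 + 8 in 4Qvs4W, peaks planted inside 3 and 6 of those DE genes
respectively plus 8 intergenic background peaks, compartment switches over
4 and 7 genes plus 4 background switches, an 8-gene curated list half
drawn from the day-4 DE genes, and 5 DMRs with an `associated_gene`
relation. Scales are toy (a real Hi-C switch bin is 100 kb; real studies
have thousands of DEGs) — the generator tests *integration and query
semantics*, not statistical realism: p-values and fold-changes are
uniform draws with no biology in them, and passing fixtures says nothing
about upstream differential analyses.

Planted structure is constructed, never sampled-and-checked: a planted
peak is a sub-interval of its gene, background features sit strictly
inside intergenic gaps (20 bp margins), and switches span a gene start
without reaching the previous gene (gaps exceed the maximal upstream
extension). Requests that are geometrically infeasible (more planted peaks
than DE genes, no gap wide enough) raise instead of degrading. Expected
answers are nevertheless recomputed at generation time by brute-force
enumeration over the emitted tables, so the truth model does not trust the
construction. Everything derives from one `random.Random(seed)`;
regeneration is byte-identical.

## Reference reproduction suites

The two use-case modules encode the published counting results as
write-once constants with their queries: for the cardiomyopathy study,
691/835 up/down protein-coding DEGs, 264/207 lncRNAs, 297/523 co-regulated
genes (the source text says 524 co-down but its own supplementary table
holds 523 entries; the suite stores what the table holds) and 1453/3600
hyper/hypo DMRs; for the honeybee study, 253/382/4618/448 unique ATAC
peaks and 37/181/703/578 unique ChIP peaks per condition, and 247/325
genes overlapping compartment switches per contrast. Running these against
the real data requires the studies' supplementary workbooks and genome
GFFs (not redistributed; see `supplement_manifest()`); the offline test
suite runs the identical prepare → integrate → reproduce pipeline on
synthetic stand-ins with the same file shapes and verifies every count
against the stand-ins' known truth. Gene-to-DMR association uses the
supplementary `associated gene` column as a declared relation, matching
how the source tables are written; positional overlap with DMRs remains
available as an alternative query.

## Numerical and engineering choices

- Problem sizes in tests: overlap-oracle studies use 100 + 100 intervals
  on 3 chromosomes over a 10 kb span (interval length 0–400, so abutting
  and contained cases are frequent); the demo battery runs 25-gene
  studies over 10 seeds. These sizes give dense boundary coverage while
  keeping the rdflib join (the slow path, ~1 s per 100×100 overlap query)
  reasonable.
- Query output is deterministic: non-aggregate SELECTs are DISTINCT and
  ordered by the first projected variable; variables project in node
  insertion order.
- The reserved attribute `label` maps to `rdfs:label` (entity
  identifiers); all other properties live under
  `<namespace>/property/<label>` so the same column name in two tables
  yields one predicate.
- Degenerate inputs: empty tables are schema-only; an empty design is an
  empty batch; a query on an empty store returns zero rows, not an error;
  single-base regions (`start == end`) are valid everywhere.
- xlsx workbooks are pre-converted sheet-by-sheet to CSV
  (`usecases.xlsx_to_csv`); the core converters stay tabular-only.

## Known limitations

- The store is in-memory (rdflib); persistence is per-graph N-Triples
  export/import via the CLI project directory. Genome-scale integration
  (tens of millions of triples) wants a server-grade triplestore behind
  the same `TripleStore` contract.
- No OWL reasoning or ontology-hierarchy expansion (GO/KEGG term
  subsumption is out of scope), no SPARQL federation (`SERVICE`), no
  BAM/VCF/bigWig ingestion, no GTF.
- Overlap queries are quadratic per chromosome in the worst case; use
  `materialize-overlaps` when the same join is run repeatedly.
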