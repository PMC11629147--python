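# omigraph

**A queryable RDF integration schema for multi-omics late integration.**

Late integration combines the *results* of separately analysed single-omics
studies — lists of differentially expressed genes, differentially methylated
regions, ATAC/ChIP peaks, Hi-C compartment switches — rather than their raw
data. In practice this usually means a pile of ad-hoc join scripts, one per
biological question. `omigraph` replaces those scripts with one linked RDF
graph and a small query language over it.

It is aimed at bioinformaticians who sit on the supplementary tables of a
multi-omics study (their own or a published one) and want to ask cross-omics
questions — *which genes differential at day 4 carry an accessibility peak
and sit in a compartment switch?* — without writing a new pandas/bedtools
script per question.

## The model

Every dataset is lifted into a five-block schema:

- **Genomic features** — GFF3 entities (gene, mRNA, exon, CDS, UTR...) with
  `parent` relations forming the usual hierarchy.
- **Functional annotation** — attributes and curated gene lists that enrich
  existing entities.
- **Experimental design** — `Condition` (one experimental condition),
  `Context` (a grouping of conditions) and `Contrast` (a comparison of two
  contexts; the entity every differential result points at).
- **Differential entities** — one RDF entity per result row (DEG, DMR, ...),
  linked to its Contrast and carrying sense attributes (UP/DOWN,
  hyper/hypo).
- **Regulation entities** — located features such as peaks and compartment
  switches.

Two mechanisms glue the blocks together. First, URIs are minted
deterministically as `<namespace>/<class>/<id>`, so two tables mentioning
gene `g0007` describe one node. Second, every located entity carries a
[FALDO](http://biohackathon.org/resource/faldo) region (begin/end
`ExactPosition` nodes, strand position classes, `faldo:reference` to a
chromosome entity) plus flat `reference`/`start`/`end`/`strand` attributes,
so any two located classes are joinable on genomic overlap with no foreign
key at all.

Tables follow two conventions: the **first column** names the entity class
and holds its identifier, and a header of the form `relation@TargetClass`
(e.g. `differentiallyExpressedIn@Contrast`) declares a relation column.

Queries are graphs, not SPARQL: typed variable nodes with attribute
filters, connected by relation edges or overlap edges. The compiler
validates the graph against the merged dataset schema and emits SPARQL 1.1.
Intervals are 1-based and closed, so two regions sharing a single base
overlap; `start(a) ≤ end(b) ∧ start(b) ≤ end(a)` on a shared reference,
with containment and same-strand variants. An all-pairs Python oracle with
identical semantics backs the test suite.

## Worked example

Generate a synthetic two-timepoint queen-vs-worker study (toy genome,
DEG/ATAC/switch/DMR tables, design tables), integrate it, and verify every
planted answer:

```
$ omigraph demo demo_out --seed 7 --n-genes 25
[ok  ] atac_2Q                expected 2  observed 2
[ok  ] atac_2W                expected 4  observed 4
[ok  ] atac_4Q                expected 4  observed 4
[ok  ] atac_4W                expected 7  observed 7
[ok  ] caste_deg_atac_4Qvs4W  expected 3  observed 3
[ok  ] deg_2Qvs2W_DOWN        expected 5  observed 5
[ok  ] deg_2Qvs2W_UP          expected 6  observed 6
[ok  ] deg_4Qvs4W_DOWN        expected 8  observed 8
[ok  ] deg_4Qvs4W_UP          expected 10  observed 10
[ok  ] deg_atac_2Qvs2W        expected 5  observed 5
[ok  ] deg_atac_4Qvs4W        expected 6  observed 6
[ok  ] gene_lookup_dmr        expected 1  observed 1
[ok  ] gene_switch_2Qvs2W     expected 4  observed 4
[ok  ] gene_switch_4Qvs4W     expected 7  observed 7
14/14 queries reproduced
```

Each line is one compiled SPARQL count against its planted ground truth:
`deg_4Qvs4W_UP` counts DEG entities up-regulated in the 4Qvs4W contrast;
`deg_atac_4Qvs4W` counts genes differential in that contrast that overlap
an ATAC peak; `caste_deg_atac_4Qvs4W` adds the curated-annotation filter
(the classic "annotated ∧ differential ∧ peak-bearing" question);
`gene_lookup_dmr` is the single-gene lookup ("is this gene associated with
a hyper- or hypo-methylated region?").

The same machinery works file by file:

```
omigraph integrate --kind gff3 demo_out/genes.gff3
omigraph integrate --kind table demo_out/deg.csv demo_out/atac.csv
omigraph integrate --kind design demo_out
omigraph query my_query.json --show-sparql   # print compiled SPARQL
omigraph query my_query.json --count gene    # COUNT(DISTINCT ?gene)
```

where `my_query.json` is a saved query graph, e.g. genes named `GENE0011`
with their associated DMRs and methylation sense:

```json
{"nodes": [{"var": "dmr",  "class": "DMR", "selected": ["methylation_sense"]},
           {"var": "gene", "class": "gene", "filters": [["Name", "=", "GENE0011"]]}],
 "edges": [{"from": "dmr", "to": "gene", "kind": "relation",
            "relation": "associated_gene"}]}
```

## Reference studies

`omigraph usecase hcm ...` and `omigraph usecase honeybee ...` implement
the preprocessing (spreadsheet concatenation with added Contrast / sense /
Condition columns) and the counting-query suites for two published
multi-omics studies: a human hypertrophic-cardiomyopathy study
(Control/HCM/Fetus cohorts; DEGs, lncRNAs, co-regulated genes, DMRs, TF
motifs) and a honeybee caste-differentiation study (2Q/2W/4Q/4W
conditions; DEGs, Hi-C A/B switches, ATAC and ChIP peaks, curated gene
lists). The supplementary tables and genome GFFs are not redistributed;
`omigraph.usecases.supplement_manifest()` lists the expected files and
sources. Synthetic stand-ins with the same file shapes
(`write_hcm_standin`, `write_honeybee_standin`) keep the whole
prepare → integrate → reproduce pipeline testable offline.

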