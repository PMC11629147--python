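"""Self-contained synthetic inputs with known ground-truth query answers.

The generator emulates the shape of a late-integration study: a toy GFF3
genome annotation (gene → mRNA → exon/CDS hierarchies on a few
chromosomes), differential-expression rows attached to Contrasts with an
UP/DOWN sense, ATAC peaks per Condition, compartment-switch regions per
Contrast, DMRs with an associated-gene relation, and a manually curated
gene list — mirroring a two-timepoint queen-vs-worker design
(conditions 2Q/2W/4Q/4W, contrasts 2Qvs2W and 4Qvs4W).

Overlaps are *constructed*, never sampled-and-checked: peaks and switch
regions are either placed inside a chosen gene or strictly inside an
intergenic gap, so every expected count is exact.  All expected answers
are nevertheless recomputed by brute-force enumeration at generation time
(:func:`omigraph.query_builder.brute_force_overlap` plus plain set
arithmetic), so the truth model never trusts the construction.

Everything is deterministic per seed, byte-identical on regeneration.
"""

from __future__ import annotations

import io
import json
import os
import random
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError
from .query_builder import QueryEdge, QueryGraph, QueryNode, brute_force_overlap
from .schema_core import Region, Strand

CONDITIONS = ("2Q", "2W", "4Q", "4W")
CONTRASTS = {"2Qvs2W": ("2Q", "2W"), "4Qvs4W": ("4Q", "4W")}

CASTE_ANNOTATION = "caste_differentiation"


@dataclass
class FixtureSpec:
    """Row counts and planted structure for the omics tables.

    Defaults give a small but non-trivial study: tens of DEGs per
    contrast, more planted epigenetic signal at day 4 than day 2 (the
    honeybee-style asymmetry), and a curated gene list intersecting the
    differential genes.
    """

    deg_per_contrast: dict = field(
        default_factory=lambda: {"2Qvs2W": (6, 5), "4Qvs4W": (10, 8)}
    )
    atac_planted: dict = field(default_factory=lambda: {"2Qvs2W": 3, "4Qvs4W": 6})
    atac_background: int = 8
    switch_genes: dict = field(default_factory=lambda: {"2Qvs2W": 4, "4Qvs4W": 7})
    switch_background: int = 4
    n_caste_genes: int = 8
    n_dmr: int = 5


@dataclass
class TruthModel:
    seed: int
    genes: list  # (id, Region, name)
    feature_count: int = 0
    gff3: str = ""
    tables: dict = field(default_factory=dict)  # filename -> CSV text
    expected: dict = field(default_factory=dict)  # query name -> int
    lookup_gene_name: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n_genes": len(self.genes),
                "feature_count": self.feature_count,
                "expected": self.expected,
                "lookup_gene_name": self.lookup_gene_name,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# toy genome annotation

_MIN_GAP, _MAX_GAP = 500, 2000
_MIN_GENE, _MAX_GENE = 500, 3000


def generate_toy_annotation(
    n_genes: int, n_refs: int, seed: int
) -> tuple[str, TruthModel]:
    """Deterministic toy GFF3: non-overlapping genes laid left to right on
    ``n_refs`` chromosomes, each with 1–2 mRNAs carrying exons and a CDS."""
    if n_genes < 1 or n_refs < 1:
        raise ValidationError("need at least one gene and one reference")
    rng = random.Random(seed)
    refs = [f"chr{i + 1}" for i in range(n_refs)]
    cursor = {r: 0 for r in refs}
    lines = ["##gff-version 3"]
    genes: list[tuple[str, Region, str]] = []
    feature_count = 0

    def row(ref, src, ftype, start, end, strand, attrs):
        lines.append(
            "\t".join([ref, src, ftype, str(start), str(end), ".", strand, ".", attrs])
        )

    for i in range(n_genes):
        ref = refs[i % n_refs]
        start = cursor[ref] + rng.randint(_MIN_GAP, _MAX_GAP)
        end = start + rng.randint(_MIN_GENE, _MAX_GENE) - 1
        cursor[ref] = end
        strand = rng.choice("+-")
        gid = f"g{i + 1:04d}"
        name = f"GENE{i + 1:04d}"
        genes.append((gid, Region(ref, start, end, Strand(strand)), name))
        row(ref, "toy", "gene", start, end, strand,
            f"ID={gid};Name={name};biotype=protein_coding")
        feature_count += 1
        for t in range(rng.randint(1, 2)):
            tid = f"{gid}.t{t + 1}"
            row(ref, "toy", "mRNA", start, end, strand, f"ID={tid};Parent={gid}")
            feature_count += 1
            n_exons = rng.randint(1, 3)
            bounds = sorted(rng.sample(range(start, end + 1), 2 * n_exons))
            for e in range(n_exons):
                ex_s, ex_e = bounds[2 * e], bounds[2 * e + 1]
                row(ref, "toy", "exon", ex_s, ex_e, strand,
                    f"ID={tid}.e{e + 1};Parent={tid}")
                feature_count += 1
            span = end - start + 1
            row(ref, "toy", "CDS", start + span // 4, end - span // 4, strand,
                f"ID={tid}.cds;Parent={tid}")
            feature_count += 1

    gff3 = "\n".join(lines) + "\n"
    return gff3, TruthModel(seed=seed, genes=genes, feature_count=feature_count, gff3=gff3)


# ---------------------------------------------------------------------------
# omics tables


def _csv(headers: list[str], rows: list[list]) -> str:
    import csv as _csvmod

    buf = io.StringIO()
    w = _csvmod.writer(buf, lineterminator="\n")
    w.writerow(headers)
    w.writerows(rows)
    return buf.getvalue()


def _intergenic_gaps(genes, margin: int = 20, min_width: int = 60):
    """Intervals strictly between consecutive genes of one reference."""
    by_ref: dict[str, list[Region]] = {}
    for _, region, _ in genes:
        by_ref.setdefault(region.reference, []).append(region)
    gaps = []
    for ref in sorted(by_ref):
        regions = sorted(by_ref[ref], key=lambda r: r.start)
        prev_end = 0
        for r in regions:
            lo, hi = prev_end + margin + 1, r.start - margin - 1
            if hi - lo + 1 >= min_width:
                gaps.append((ref, lo, hi))
            prev_end = r.end
    return gaps


def generate_omics_tables(
    truth: TruthModel, spec: Optional[FixtureSpec] = None, seed: Optional[int] = None
) -> TruthModel:
    """Fill ``truth`` with omics/design tables and brute-force expected
    answers for the standard query battery (per-contrast DEG counts,
    per-condition peak counts, DEG-over-peak gene counts, gene-over-switch
    counts, curated-list intersections, a single-gene DMR lookup)."""
    spec = spec or FixtureSpec()
    rng = random.Random(truth.seed if seed is None else seed)
    genes = truth.genes
    gene_ids = [g[0] for g in genes]
    gene_by_id = {g[0]: g for g in genes}

    # ---- differential expression ----
    de_genes: dict[str, list[str]] = {}
    deg_rows = []
    counter = 0
    for contrast, (n_up, n_down) in spec.deg_per_contrast.items():
        n = n_up + n_down
        if n > len(genes):
            raise ValidationError(
                f"contrast {contrast}: {n} DEGs requested but only {len(genes)} genes"
            )
        chosen = rng.sample(gene_ids, n)
        de_genes[contrast] = chosen
        for k, gid in enumerate(chosen):
            counter += 1
            sense = "UP" if k < n_up else "DOWN"
            region = gene_by_id[gid][1]
            lfc = rng.uniform(1.0, 6.0) * (1 if sense == "UP" else -1)
            pval = rng.uniform(1e-8, 1e-3)
            deg_rows.append(
                [
                    f"deg{counter:04d}", gid, region.reference, region.start,
                    region.end, region.strand.value, f"{lfc:.3f}",
                    f"{pval:.3e}", f"{pval * rng.uniform(1.0, 5.0):.3e}",
                    contrast, sense,
                ]
            )
    truth.tables["deg.csv"] = _csv(
        ["DEG", "gene@gene", "chromosome", "start", "end", "strand",
         "log2_fold_change", "pvalue", "FDR", "differentiallyExpressedIn@Contrast",
         "regulation_sense"],
        deg_rows,
    )

    # ---- ATAC peaks: planted inside chosen DE genes + intergenic background ----
    gaps = _intergenic_gaps(genes)
    atac_rows = []
    peak_regions: list[tuple[str, Region]] = []
    pk = 0

    def add_peak(ref, s, e, condition):
        nonlocal pk
        pk += 1
        pid = f"atac{pk:04d}"
        region = Region(ref, s, e)
        peak_regions.append((pid, region))
        atac_rows.append(
            [pid, ref, s, e, condition, f"{rng.uniform(2, 20):.2f}",
             f"{rng.uniform(1e-9, 1e-4):.3e}"]
        )

    for contrast, k in spec.atac_planted.items():
        pool = de_genes.get(contrast, [])
        if k > len(pool):
            raise ValidationError(
                f"cannot plant {k} peaks in {len(pool)} DE genes of {contrast}"
            )
        for gid in rng.sample(pool, k):
            r = gene_by_id[gid][1]
            s = rng.randint(r.start, max(r.start, r.end - 60))
            e = min(r.end, s + rng.randint(30, 200))
            add_peak(r.reference, s, e, rng.choice(CONTRASTS[contrast]))
    if (spec.atac_background > 0 or spec.switch_background > 0) and not gaps:
        raise ValidationError("no intergenic gap wide enough for background features")
    for _ in range(spec.atac_background):
        ref, lo, hi = rng.choice(gaps)
        s = rng.randint(lo, hi - 30)
        e = min(hi, s + rng.randint(20, 50))
        add_peak(ref, s, e, rng.choice(CONDITIONS))
    truth.tables["atac.csv"] = _csv(
        ["ATACpeak", "chromosome", "start", "end", "measuredIn@Condition",
         "fold_change", "qvalue"],
        atac_rows,
    )

    # ---- compartment switches: planted over gene starts + background ----
    switch_rows = []
    switch_regions: dict[str, list[tuple[str, Region]]] = {c: [] for c in CONTRASTS}
    sw = 0
    for contrast, m in spec.switch_genes.items():
        if m > len(genes):
            raise ValidationError(f"{m} switch genes requested, {len(genes)} available")
        for gid in rng.sample(gene_ids, m):
            r = gene_by_id[gid][1]
            sw += 1
            s = max(1, r.start - rng.randint(0, 100))
            e = r.start + rng.randint(50, 300)
            region = Region(r.reference, s, e)
            switch_regions[contrast].append((f"sw{sw:04d}", region))
            switch_rows.append(
                [f"sw{sw:04d}", r.reference, s, e, contrast,
                 rng.choice(["AtoB", "BtoA"]), f"{rng.uniform(0.1, 3.0):.3f}"]
            )
    for _ in range(spec.switch_background):
        contrast = rng.choice(sorted(CONTRASTS))
        ref, lo, hi = rng.choice(gaps)
        sw += 1
        s = rng.randint(lo, hi - 30)
        e = min(hi, s + rng.randint(20, 50))
        switch_regions[contrast].append((f"sw{sw:04d}", Region(ref, s, e)))
        switch_rows.append(
            [f"sw{sw:04d}", ref, s, e, contrast,
             rng.choice(["AtoB", "BtoA"]), f"{rng.uniform(0.1, 3.0):.3f}"]
        )
    truth.tables["switch.csv"] = _csv(
        ["switch_region", "chromosome", "start", "end", "switchedIn@Contrast",
         "switch_direction", "score"],
        switch_rows,
    )

    # ---- curated caste-gene list: half from the day-4 peak genes ----
    day4 = de_genes.get("4Qvs4W", [])
    core = rng.sample(day4, min(len(day4), spec.n_caste_genes // 2))
    rest_pool = [g for g in gene_ids if g not in core]
    caste = core + rng.sample(rest_pool, max(0, spec.n_caste_genes - len(core)))
    truth.tables["caste.csv"] = _csv(
        ["gene", "annotation"], [[g, CASTE_ANNOTATION] for g in sorted(caste)]
    )

    # ---- DMRs with an associated-gene relation ----
    dmr_rows = []
    dmr_gene_choices = [rng.choice(gene_ids) for _ in range(spec.n_dmr)]
    for i, gid in enumerate(dmr_gene_choices, start=1):
        r = gene_by_id[gid][1]
        s = rng.randint(r.start, max(r.start, r.end - 60))
        e = min(r.end, s + rng.randint(40, 300))
        dmr_rows.append(
            [f"dmr{i:04d}", r.reference, s, e, gid,
             rng.choice(["hyper", "hypo"]), "4Qvs4W"]
        )
    truth.tables["dmr.csv"] = _csv(
        ["DMR", "chromosome", "start", "end", "associated_gene@gene",
         "methylation_sense", "differentiallyMethylatedIn@Contrast"],
        dmr_rows,
    )

    # ---- experimental design ----
    truth.tables["conditions.csv"] = _csv(
        ["Condition", "description"],
        [[c, f"{'queen' if 'Q' in c else 'worker'} day {c[0]}"] for c in CONDITIONS],
    )
    truth.tables["contexts.csv"] = _csv(
        ["Context", "condition@Condition"], [[c, c] for c in CONDITIONS]
    )
    truth.tables["contrasts.csv"] = _csv(
        ["Contrast", "context_A@Context", "context_B@Context"],
        [[name, a, b] for name, (a, b) in CONTRASTS.items()],
    )

    # ---- expected answers, by independent enumeration ----
    gene_regions = [(gid, region) for gid, region, _ in genes]
    genes_with_peak = {g for g, _ in brute_force_overlap(gene_regions, peak_regions)}
    expected = {}
    for contrast in spec.deg_per_contrast:
        rows = [r for r in deg_rows if r[9] == contrast]
        expected[f"deg_{contrast}_UP"] = len({r[0] for r in rows if r[10] == "UP"})
        expected[f"deg_{contrast}_DOWN"] = len({r[0] for r in rows if r[10] == "DOWN"})
        expected[f"deg_atac_{contrast}"] = len(set(de_genes[contrast]) & genes_with_peak)
    for condition in CONDITIONS:
        expected[f"atac_{condition}"] = len({r[0] for r in atac_rows if r[4] == condition})
    for contrast in CONTRASTS:
        hit = {g for g, _ in brute_force_overlap(gene_regions, switch_regions[contrast])}
        expected[f"gene_switch_{contrast}"] = len(hit)
    expected["caste_deg_atac_4Qvs4W"] = len(
        set(caste) & set(de_genes.get("4Qvs4W", [])) & genes_with_peak
    )
    if dmr_rows:
        lookup_gid = dmr_gene_choices[0]
        truth.lookup_gene_name = gene_by_id[lookup_gid][2]
        expected["gene_lookup_dmr"] = len(
            {row[0] for row in dmr_rows if row[4] == lookup_gid}
        )
    truth.expected = expected
    return truth


# ---------------------------------------------------------------------------
# the query battery matching the expected answers


def build_truth_queries(truth: TruthModel) -> dict[str, tuple[QueryGraph, str]]:
    """One QueryGraph per named expected answer; (graph, counted var)."""
    queries: dict[str, tuple[QueryGraph, str]] = {}

    def contrast_node(name: str) -> QueryNode:
        return QueryNode("contrast", "Contrast", [("label", "=", name)])

    for name in truth.expected:
        if name.startswith("deg_atac_"):
            contrast = name[len("deg_atac_"):]
            q = QueryGraph(
                [
                    QueryNode("gene", "gene"),
                    QueryNode("deg", "DEG"),
                    contrast_node(contrast),
                    QueryNode("peak", "ATACpeak"),
                ],
                [
                    QueryEdge("deg", "gene", "relation", "gene"),
                    QueryEdge("deg", "contrast", "relation", "differentiallyExpressedIn"),
                    QueryEdge("gene", "peak", "overlap"),
                ],
            )
            queries[name] = (q, "gene")
        elif name.startswith("deg_"):
            contrast, sense = name[len("deg_"):].rsplit("_", 1)
            q = QueryGraph(
                [
                    QueryNode("deg", "DEG", [("regulation_sense", "=", sense)]),
                    contrast_node(contrast),
                ],
                [QueryEdge("deg", "contrast", "relation", "differentiallyExpressedIn")],
            )
            queries[name] = (q, "deg")
        elif name.startswith("atac_"):
            condition = name[len("atac_"):]
            q = QueryGraph(
                [
                    QueryNode("peak", "ATACpeak"),
                    QueryNode("condition", "Condition", [("label", "=", condition)]),
                ],
                [QueryEdge("peak", "condition", "relation", "measuredIn")],
            )
            queries[name] = (q, "peak")
        elif name.startswith("gene_switch_"):
            contrast = name[len("gene_switch_"):]
            q = QueryGraph(
                [
                    QueryNode("gene", "gene"),
                    QueryNode("sw", "switch_region"),
                    contrast_node(contrast),
                ],
                [
                    QueryEdge("sw", "contrast", "relation", "switchedIn"),
                    QueryEdge("gene", "sw", "overlap"),
                ],
            )
            queries[name] = (q, "gene")
        elif name == "caste_deg_atac_4Qvs4W":
            q = QueryGraph(
                [
                    QueryNode("gene", "gene", [("annotation", "=", CASTE_ANNOTATION)]),
                    QueryNode("deg", "DEG"),
                    contrast_node("4Qvs4W"),
                    QueryNode("peak", "ATACpeak"),
                ],
                [
                    QueryEdge("deg", "gene", "relation", "gene"),
                    QueryEdge("deg", "contrast", "relation", "differentiallyExpressedIn"),
                    QueryEdge("gene", "peak", "overlap"),
                ],
            )
            queries[name] = (q, "gene")
        elif name == "gene_lookup_dmr":
            q = QueryGraph(
                [
                    QueryNode("dmr", "DMR", selected=["methylation_sense"]),
                    QueryNode("gene", "gene", [("Name", "=", truth.lookup_gene_name)]),
                ],
                [QueryEdge("dmr", "gene", "relation", "associated_gene")],
            )
            queries[name] = (q, "dmr")
    return queries


def random_located_features(
    rng: random.Random,
    class_label: str,
    n: int,
    n_refs: int = 3,
    span: int = 10_000,
    max_len: int = 400,
) -> list[tuple[str, Region]]:
    """Uniform random intervals (mixed strands, unknown included) for
    overlap-semantics testing."""
    feats = []
    for i in range(n):
        ref = f"chr{rng.randrange(n_refs) + 1}"
        start = rng.randrange(1, span)
        feats.append(
            (
                f"{class_label}{i}",
                Region(ref, start, start + rng.randrange(0, max_len),
                       Strand(rng.choice("+-."))),
            )
        )
    return feats


def load_located_features(store, class_label: str, features) -> None:
    """Load bare (id, Region) features as entities of a located class —
    the minimal dataset an overlap query needs."""
    from rdflib import Literal, RDF, RDFS, URIRef

    from .schema_core import (
        EntityClassDef,
        PropertyDef,
        TripleBatch,
        mint_class_uri,
        mint_entity_uri,
        region_triples,
    )

    ns = store.namespace
    batch = TripleBatch(URIRef(f"{ns.rstrip('/')}/graph/{class_label}"))
    class_uri = mint_class_uri(ns, class_label)
    for fid, region in features:
        subject = mint_entity_uri(ns, class_label, fid)
        batch.add(subject, RDF.type, class_uri)
        batch.add(subject, RDFS.label, Literal(fid))
        batch.extend(region_triples(subject, region, ns, batch.graph_name))
    schema = [
        EntityClassDef(
            class_label, class_uri, True,
            [PropertyDef("label", "attribute", "string"),
             PropertyDef("reference", "attribute", "string"),
             PropertyDef("start", "attribute", "integer"),
             PropertyDef("end", "attribute", "integer"),
             PropertyDef("strand", "attribute", "string")],
        )
    ]
    store.load_graph(batch, schema, source=class_label)


# ---------------------------------------------------------------------------
# filesystem + integration helpers

TABLE_FILES = ("deg.csv", "atac.csv", "switch.csv", "dmr.csv", "caste.csv")
DESIGN_FILES = ("conditions.csv", "contexts.csv", "contrasts.csv")


def write_fixture_dir(
    outdir: str,
    seed: int,
    n_genes: int = 30,
    n_refs: int = 3,
    spec: Optional[FixtureSpec] = None,
) -> TruthModel:
    """Generate annotation + tables and write everything under ``outdir``."""
    gff3, truth = generate_toy_annotation(n_genes, n_refs, seed)
    truth = generate_omics_tables(truth, spec)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genes.gff3"), "w") as fh:
        fh.write(gff3)
    for fname, text in truth.tables.items():
        with open(os.path.join(outdir, fname), "w") as fh:
            fh.write(text)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
    return truth


def integrate_fixture_dir(store, path: str) -> None:
    """Convert and load a fixture directory into a triple store."""
    from rdflib import URIRef

    from .converters import (
        build_design_graph,
        convert_gff3,
        convert_table,
        design_schema,
        read_design_dir,
        read_table,
    )

    ns = store.namespace
    with open(os.path.join(path, "genes.gff3")) as fh:
        batch, schema = convert_gff3(fh, ns)
    store.load_graph(batch, schema, source="genes.gff3")
    for fname in TABLE_FILES:
        fpath = os.path.join(path, fname)
        if not os.path.exists(fpath):
            continue
        table = read_table(fpath)
        batch, schema = convert_table(
            table, ns, URIRef(f"{ns.rstrip('/')}/graph/{fname}")
        )
        store.load_graph(batch, schema, source=fname)
    design = read_design_dir(path)
    store.load_graph(build_design_graph(design, ns), design_schema(ns), source="design")
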