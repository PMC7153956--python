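# kgreview

Structured-review knowledge graphs for hypothesis generation in focused
biomedical domains — built for the situation rare-disease researchers face:
the relevant evidence is scattered across curated databases, model-organism
resources, regulatory-interaction collections and experimental datasets,
and a free-text review of it cannot be queried by a computer.

`kgreview` assembles a *structured review*: a typed, provenance-tracked
knowledge graph focused on a seed set of concepts (genes, a disease, a
metabolite), built entirely from file-based source tables so every review
is reproducible and versionable. On top of the assembled graph it provides
a metapath query engine that enumerates mechanistic hypotheses as typed
paths.

## What it does

* **Data model** — nodes are concepts with compact identifiers (CURIEs,
  e.g. `HGNC:17646`) in eight semantic groups (gene, disease/phenotype,
  pathway, anatomy, variant, genotype, chemical, organism); edges are
  statements `(subject, property, object)` carrying the relation label,
  an ontology relation id/URI, supporting sentence and reference URIs.
  Statements are deduplicated on `(subject, property, object)`; repeated
  assertions merge their provenance.
* **Ingestion** — readers for edge/node TSV tables, GMT gene-set files
  (TF regulons), differential-expression tables, cross-reference maps,
  ortholog pair + ortholog–phenotype tables and relation-semantics maps.
* **Normalization** — genes are *rewritten* onto a preferred namespace
  (HGNC) via cross-references; diseases are *linked* to MONDO through
  `skos:exactMatch` edges, preserving the original identifier; relation
  labels are mapped to ontology terms; node annotation fills only empty
  fields.
* **Assembly** — seed-driven neighborhood expansion (breadth-first,
  direction-agnostic), ortholog + ortholog-phenotype expansion, and
  conversion of a differential-expression table into edges
  (strict filter: |fold change| > 1.5 and FDR < 0.05) linking the
  perturbed gene to each significantly changed gene.
* **Export** — Neo4j bulk-import CSV (`id:ID`, `:LABEL`, `:START_ID`,
  `:TYPE`, `:END_ID` convention), a lossless TSV dialect, and RDF
  N-Triples with CURIE→URI prefix expansion; all byte-deterministic.
* **Metapath queries** — templates alternate node constraints (anchor id,
  semantic groups, taxon, id prefixes) and edge constraints (relation
  ids/labels, direction); the engine enumerates **all** simple paths
  matching the template and summarizes node frequencies per path
  position. It is validated against an independent brute-force
  enumeration oracle.
* **Synthetic fixtures** — deterministic generators for multi-typed
  graphs, planted template instances with exact ground truth, and
  expression tables whose pass/fail sets are known by construction.

## Worked example

Build a tiny review around NGLY1 and query it for gene–gene paths:

```python
from kgreview import KnowledgeGraph, compile_template, enumerate_paths, graph_summary
from kgreview.seeds import seed_graph
from kgreview.datamodel import parse_curie, EdgeRecord

g = seed_graph()                       # the nine bundled seed concepts
g.add_edge(EdgeRecord(
    subject=parse_curie("HGNC:17646"),      # NGLY1
    property_id=parse_curie("RO:0002434"),
    object=parse_curie("HGNC:7781"),        # NFE2L1
    property_label="interacts with",
))
g.add_edge(EdgeRecord(
    subject=parse_curie("HGNC:7781"),
    property_id=parse_curie("RO:0002434"),
    object=parse_curie("HGNC:633"),         # AQP1
    property_label="regulates",
))

print(graph_summary(g))
template = compile_template({
    "nodes": [{"id": "HGNC:17646"}, {"groups": ["GENE"]}, {"id": "HGNC:633"}],
    "edges": [{"labels": ["interacts with"]}, {"labels": ["regulates"]}],
})
for p in enumerate_paths(g, template):
    print(p.nodes, p.directions)
```

prints

```
{'n_nodes': 9, 'n_edges': 2, 'nodes_by_group': {'GENE': 7, 'CHEMICAL': 1, 'DISO': 1}, 'edges_by_label': {'interacts with': 1, 'regulates': 1}, 'n_relation_types': 2}
('HGNC:17646', 'HGNC:7781', 'HGNC:633') ('forward', 'forward')
```

— nine seed nodes (seven genes, the metabolite GlcNAc, the disease), and
one matched path: the hypothesis that NGLY1 influences AQP1 expression
through the transcription factor NFE2L1.

The same flow is available from the shell:

```bash
kgreview build --config review.yaml --out graph/
kgreview query --graph graph/ --template regulatory_hypothesis.json --out paths.tsv
kgreview summarize --graph graph/ --template regulatory_hypothesis.json --out summary.tsv
kgreview export --graph graph/ --format neo4j-csv --out neo4j/
```

Two editable query-topology fixtures ship with the package
(`kgreview.seeds.REGULATORY_TEMPLATE`, `kgreview.seeds.PHENOTYPE_TEMPLATE`):
a length-four regulatory topology linking the fly NGLY1 ortholog to human
AQP1 through regulation and orthology, and a phenotype topology relating
candidate AQP1 regulators to disease phenotypes via shared `has phenotype`
edges.

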