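# Methods

## The structured-review model

A structured review is a directed multigraph of provenanced statements.
Nodes are biomedical concepts identified by CURIEs (`prefix:local_id`,
split on the first colon so local ids may themselves contain colons) and
typed with one of eight coarse semantic groups — GENE, DISO (diseases and
phenotypes together), PATHWAY, ANATOMY, VARIANT, GENOTYPE, CHEMICAL,
ORGANISM — plus UNKNOWN for endpoints seen only in edges. Edges carry a
relation label, an ontology relation identifier and URI, the supporting
sentence and the reference URIs that make each assertion traceable.

**Statement identity.** An edge is identified by
`(subject, property_id, object)`; provenance is excluded from the key.
Re-adding an existing statement merges it: reference URIs take the
deduplicated union in first-seen order and *distinct* supporting texts are
joined with `" | "` in first-seen order. Joining only distinct texts is
what makes insertion idempotent and order-independent — a multiset of
edges yields the same graph under any insertion order, which merging in
turn inherits (merging is associative, commutative and idempotent up to
graph equality). Graph edges are stored directed as asserted; direction
handling is deferred to query time. One exception: orthology edges built
by the ortholog expander are stored in lexicographic endpoint order,
because orthology is symmetric and the canonical direction is what lets
repeated expansion from either partner deduplicate to a single statement.

**Endpoint stubs.** Edges may arrive before their nodes; missing
endpoints are auto-created as UNKNOWN-group stubs with the local id as
preferred label. Annotation later upgrades stubs (group, labels,
description) but never overwrites a curated non-empty field; the one
asymmetry is that a stub's fallback preflabel always yields to a real
label. After annotation every node has a non-empty preflabel (fallback:
the local id).

## Normalization

Two deliberately different strategies:

* **Genes are rewritten.** A cross-reference multimap sends gene ids onto
  the preferred namespace (HGNC for human). An identifier is considered
  when it belongs to a GENE node or appears in the map. Multiple
  candidates are resolved to the lexicographically smallest serialization
  — determinism over cleverness — and every such case is reported with
  its alternatives for manual inspection. Unmapped ids are kept and
  counted; the report satisfies
  `rewritten + unmapped + ambiguous = considered`. Edge count is
  preserved exactly.
* **Diseases are linked.** Disease ids stay as asserted; a
  `skos:exactMatch` edge (property URI
  `http://www.w3.org/2004/02/skos/core#exactMatch`, supporting text
  `id-normalization`) connects each mapped DISO node to its MONDO
  counterpart, stubbing the MONDO node if new. With several candidates
  the same lexicographic tie-break picks the link target.

Relation labels are resolved against a curated two-way map
(`label → (relation id, URI)`). Builders that know only a human-readable
label stamp edges with the sentinel `BKR:unmapped`; mapping fills in real
ids where the table has an entry and reports the labels it cannot
resolve. All normalization passes are total and idempotent.

## Assembly pipeline

`assemble_review` runs: ingest each declared source → per-source relation
mapping and gene rewriting → merge → seed neighborhood expansion →
ortholog expansion → disease linking → annotation, and emits a manifest
(source paths and row counts, normalization tallies, graph summary,
config echo, timestamp) so a review build is a reproducible, versionable
artifact. Reruns of the same configuration produce byte-identical graph
exports.

* **Neighborhood expansion** is breadth-first from the seed set ignoring
  edge direction ("has an explicit relationship to a seed" does not care
  which way the statement was asserted), keeping the subgraph induced by
  all nodes within the hop radius; zero hops returns the seeds alone with
  no edges. Seeds absent from the source are warned about, never fatal.
  Node sets are monotone in the hop count.
* **Ortholog expansion** adds, for genes already in the graph, their
  ortholog partners ("in orthology relationship with") and then — only
  for *newly introduced* partners — all their phenotype annotations
  ("has phenotype"). Restricting phenotypes to new partners keeps the
  operation idempotent and prevents phenotype dumps for genes the review
  already covers through other sources.
* **Expression edges** implement the strict differential-expression
  filter |fold change| > 1.5 and FDR < 0.05 (both inequalities strict, so
  rows exactly at a boundary are excluded). Fold changes are interpreted
  on the linear scale with sign (down-regulation negative); a config
  switch accepts log2 input, compared against log2 of the threshold.
  Each passing row becomes one "interacts with" edge from the perturbed
  source gene, with the row's fold change and FDR recorded in the
  supporting text. Genes given as bare symbols (common in fly expression
  tables and GMT regulons) are wrapped in a `SYMBOL:` namespace so
  endpoint invariants hold uniformly; a cross-reference pass can rewrite
  them later.

## Export formats

Neo4j bulk-import CSV uses the `id:ID,:LABEL,...` / `:START_ID,:TYPE,
:END_ID,...` header convention with RFC 4180 quoting; `:LABEL` is the
semantic group and `:TYPE` the upper-snake-cased relation label (the
dialect forbids spaces). The TSV dialect is the lossless one — it carries
every attribute including `reference_date`, and `read(write(g)) == g`
holds exactly. The CSV dialect is exact for graphs whose relation labels
are lowercase words and whose edges carry no reference date (the label
passes through upper-snake-casing, and the bulk-import header has no date
column); the synthetic generator emits only such graphs. N-Triples output
writes one triple per statement plus one `rdfs:label` triple per labelled
node, expanding CURIEs through a prefix map (bases must end in `/` or
`#`; unmapped prefixes are an error naming the prefix); rdflib handles
term escaping and lines are sorted, so equal graphs serialize to
identical bytes. Provenance is not reified in RDF — that export targets
interoperability, not provenance exchange.

## Metapath engine

A template is L edge constraints alternating with L+1 node constraints
(L ≥ 1). Node constraints: fixed anchor id (overrides everything),
semantic groups, taxon, id prefixes; all empty = wildcard. Edge
constraints: relation ids and/or labels, direction
(`forward`/`reverse`/`any`, default `any` since review queries typically
traverse regulatory and orthology edges irrespective of storage
direction). Matching paths are **simple** (no repeated node). A matched
path records node ids, statement keys and the direction each edge was
travelled; with `any` constraints a single undirected connection can
legitimately yield one match per traversal orientation.

`skos:exactMatch` edges match only when a constraint names them
explicitly (by id or label); wildcard edge constraints skip them, because
identifier-identity links are not mechanistic hypotheses.

The engine is a constrained depth-first expansion over per-node edge
indexes, started from the anchored end (a template anchored only at its
last position is searched reversed and the results flipped), pruning on
edge and node constraints at every step. Results are sorted by node-id
sequence then statement-key sequence, so enumeration order is
deterministic; an optional limit truncates the list and sets a flag.
Correctness is defined by — and tested against — an independent
brute-force oracle that walks every simple path by trying every edge of
the graph at each step and filters with a separate implementation of the
constraint semantics.

Path summaries count node occurrences per path position, excluding
anchored endpoint positions (anchors are constants of the query, not
findings); rows are ordered by position, descending count, then id. When
the template is not supplied, an endpoint position is treated as anchored
if all paths agree on its node. Without a group filter the counts at
each reported position sum to the number of paths.

## Synthetic data

The generator emulates the *shape* of review inputs, not their content:
multi-typed graphs with configurable node counts per semantic group and
named relation types with typed endpoints, edges drawn uniformly without
replacement among type-compatible pairs (self-loops excluded; requesting
more edges than distinct statements is an error). Planted template
instances use fresh intermediate nodes per instance, so each instance is
a distinct guaranteed match and recall on planted paths is well defined;
background edges may create additional legitimate matches, which is why
planted instances bound the match count from below while *equality* of
the full result set is checked against the oracle. Expression tables
place exactly `n_de` rows strictly beyond both thresholds and the rest
strictly outside, with a share of failing rows exactly on a boundary to
exercise the strict inequalities. Everything is deterministic under a
fixed seed.

Default validation sizes (chosen as comfortable desk-scale workloads):
oracle-equivalence on 100 random graphs of up to 40 nodes with 4 semantic
groups, 3 relation types and random templates of length 1–4; planted-path
recovery on 20 replicates of 200-node graphs (100 genes, 60
diseases/phenotypes, 25 pathways, 15 chemicals; 550 background edges)
with 10 planted instances of a length-four doubly-anchored template;
merge arithmetic on 50 graph pairs; round-trips on 50 graphs; expression
ground truth at n=100 with 17 true positives. What passing these checks
does *not* show: behaviour on real-data quirks — malformed upstream
exports, identifier drift between source versions, biological degree
distributions (hubs make wildcard queries combinatorially heavier than
uniform random graphs of equal size).

## Design choices and limitations

* Statement identity excluding provenance is a choice; alternatives
  (distinguishing statements by reference) are defensible but would make
  multi-source integration produce duplicate edges.
* The bundled seed list and the two query-topology JSON fixtures are
  editable inputs, not hard-coded truth; the exact slot-by-slot edge
  composition of the published length-four regulatory topology is a
  reconstruction.
* No ontology reasoning (no subsumption or transitive closure), no fuzzy
  string matching in normalization, no path ranking or degree-weighted
  scoring, no live API clients and no database server management — the
  CSV/RDF exports are the hand-off points to Neo4j and SPARQL tooling.
* Wildcard templates on dense graphs can enumerate exponentially many
  simple paths; the `limit` parameter exists for interactive use, and
  anchoring at least one endpoint is the intended usage for long
  templates.
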