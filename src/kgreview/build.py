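"""Graph assembly: seed-driven expansion and topic-network integration.

A structured review is assembled by (i) ingesting topic-specific networks
from files, (ii) normalizing identifiers and relation semantics, (iii)
restricting to the neighborhood of a seed concept set, (iv) expanding with
model-organism orthologs and their phenotypes, (v) converting a
differential-expression table into edges linking the perturbed gene to
each significantly changed gene, and (vi) merging everything under
statement-key deduplication.  :func:`assemble_review` drives the whole
pipeline from a declarative configuration and emits a run manifest for
versioned reproducibility.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from typing import Any, Optional, Sequence

import networkx as nx
import yaml

from .datamodel import (
    Curie,
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
    as_curie,
    graph_summary,
    parse_curie,
    statement_key,
)
from .errors import ConfigurationError, InputError, ValidationError
from .ingest import (
    ExpressionRow,
    OrthologTable,
    RegulonSet,
    read_edge_table,
    read_expression_table,
    read_gmt_regulons,
    read_node_table,
    read_ortholog_table,
    read_relation_map,
    read_xref_table,
)
from .normalize import (
    UNMAPPED_RELATION_ID,
    annotate_nodes,
    link_disease_ids,
    map_relation_semantics,
    normalize_gene_ids,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReviewConfig",
    "merge_networks",
    "neighborhood_expansion",
    "expand_orthologs",
    "build_expression_edges",
    "build_regulon_edges",
    "assemble_review",
]

# fixed relation labels used by the builders; ontology ids are attached by
# the relation-semantics map during normalization
INTERACTS_WITH = "interacts with"
ORTHOLOGY_LABEL = "in orthology relationship with"
HAS_PHENOTYPE = "has phenotype"
REGULATES = "regulates"

DEFAULT_FOLD_CHANGE_MIN = 1.5
DEFAULT_FDR_MAX = 0.05


@dataclass
class SourceDecl:
    """One declared input: a path, a reader kind and reader options."""

    path: str
    kind: str  # edges | nodes | gmt | expression | orthologs
    options: dict[str, Any] = dc_field(default_factory=dict)


@dataclass
class ReviewConfig:
    """Declarative description of one review build."""

    seeds: list[Curie]
    sources: list[SourceDecl] = dc_field(default_factory=list)
    gene_xref: Optional[str] = None
    disease_xref: Optional[str] = None
    relation_map: Optional[str] = None
    annotations: Optional[str] = None
    hops: Optional[int] = 1
    fold_change_min: float = DEFAULT_FOLD_CHANGE_MIN
    fdr_max: float = DEFAULT_FDR_MAX
    log2_fold_change: bool = False
    expression_source_gene: Optional[Curie] = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ConfigurationError("at least one seed is required")
        if self.hops is not None and self.hops < 0:
            raise ConfigurationError("hop count must be >= 0")
        if self.fold_change_min <= 0:
            raise ConfigurationError("fold_change_min must be > 0")
        if not (0 < self.fdr_max <= 1):
            raise ConfigurationError("fdr_max must be in (0, 1]")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ReviewConfig":
        """Load a configuration from YAML or JSON."""
        if not os.path.exists(path):
            raise InputError(f"config file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=os.path.dirname(str(path)))

    @classmethod
    def from_dict(
        cls, raw: dict, base_dir: str = "."
    ) -> "ReviewConfig":
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a mapping")

        def _resolve(p: Optional[str]) -> Optional[str]:
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base_dir, p)

        sources = [
            SourceDecl(
                path=_resolve(s["path"]),
                kind=s.get("kind", "edges"),
                options=dict(s.get("options", {})),
            )
            for s in raw.get("sources", [])
        ]
        for s in sources:
            if "path_phenotypes" in s.options:
                s.options["path_phenotypes"] = _resolve(
                    s.options["path_phenotypes"]
                )
            if "nodes" in s.options:
                s.options["nodes"] = _resolve(s.options["nodes"])
        seeds = [parse_curie(s) for s in raw.get("seeds", [])]
        thresholds = raw.get("thresholds", {})
        source_gene = raw.get("expression_source_gene")
        return cls(
            seeds=seeds,
            sources=sources,
            gene_xref=_resolve(raw.get("gene_xref")),
            disease_xref=_resolve(raw.get("disease_xref")),
            relation_map=_resolve(raw.get("relation_map")),
            annotations=_resolve(raw.get("annotations")),
            hops=raw.get("hops", 1),
            fold_change_min=thresholds.get(
                "fold_change_min", DEFAULT_FOLD_CHANGE_MIN
            ),
            fdr_max=thresholds.get("fdr_max", DEFAULT_FDR_MAX),
            log2_fold_change=bool(raw.get("log2_fold_change", False)),
            expression_source_gene=(
                parse_curie(source_gene) if source_gene else None
            ),
            output_dir=raw.get("output_dir", "."),
        )


# ---------------------------------------------------------------------------


def network_from(
    edges: Sequence[EdgeRecord],
    nodes: Sequence[NodeRecord] = (),
) -> KnowledgeGraph:
    """Assemble a graph from edge and node lists (nodes first)."""
    g = KnowledgeGraph()
    for n in nodes:
        g.add_node(n)
    g.add_edges(edges)
    return g


def merge_networks(
    networks: Sequence[KnowledgeGraph],
) -> KnowledgeGraph:
    """Union of topic networks under statement-key deduplication.

    Duplicate statements merge provenance; node attributes merge
    field-wise with first non-empty winning (conflicts logged).
    Associative and commutative up to graph equality.
    """
    merged = KnowledgeGraph()
    for net in networks:
        for node in net.nodes.values():
            merged.add_node(node)
        for edge in net.iter_edges():
            merged.add_edge(edge)
    return merged


def to_networkx(graph: KnowledgeGraph) -> nx.MultiDiGraph:
    """View the knowledge graph as a networkx multi-digraph.

    Edge keys are statement keys; node/edge records ride along as
    ``record`` attributes.
    """
    g = nx.MultiDiGraph()
    for key, node in graph.nodes.items():
        g.add_node(key, record=node)
    for edge in graph.iter_edges():
        g.add_edge(
            str(edge.subject),
            str(edge.object),
            key=statement_key(edge),
            record=edge,
        )
    return g


def neighborhood_expansion(
    source: KnowledgeGraph,
    seeds: Sequence[Curie],
    hops: int = 1,
) -> KnowledgeGraph:
    """Subgraph induced by breadth-first expansion around the seed set.

    Traversal ignores edge direction (a relationship to a seed counts
    whichever way it is asserted).  ``hops=0`` returns the seed nodes
    only, with no edges.  Seeds absent from the source are logged and
    skipped, never fatal.
    """
    if not seeds:
        raise ConfigurationError("seed list is empty")
    if hops < 0:
        raise ConfigurationError("hops must be >= 0")
    present = [s for s in seeds if s in source]
    for s in seeds:
        if s not in source:
            logger.warning("seed %s not present in source graph", s)

    keep: set[str] = {str(s) for s in present}
    if hops > 0 and present:
        undirected = to_networkx(source).to_undirected(as_view=True)
        for s in present:
            reached = nx.single_source_shortest_path_length(
                undirected, str(s), cutoff=hops
            )
            keep.update(reached)

    out = KnowledgeGraph()
    for key in keep:
        node = source.get_node(key)
        if node is not None:
            out.add_node(node)
    if hops > 0:
        for edge in source.iter_edges():
            if str(edge.subject) in keep and str(edge.object) in keep:
                out.add_edge(edge)
    return out


def expand_orthologs(
    graph: KnowledgeGraph, orthologs: OrthologTable
) -> KnowledgeGraph:
    """Attach orthologs of in-graph genes, then the orthologs' phenotypes.

    For every GENE node already present, ortholog pairs touching it add
    the partner gene and one orthology edge; each *newly added* partner
    then receives all its phenotype annotations as "has phenotype" edges.
    Genes not in the graph contribute nothing.  Idempotent.
    """
    from .datamodel import SemanticGroup

    graph = graph.copy()
    gene_ids = [
        n.id
        for n in graph.nodes.values()
        if n.semantic_group is SemanticGroup.GENE
    ]
    before = set(graph.nodes)
    new_partners: list[Curie] = []
    for gid in gene_ids:
        for partner, taxon in orthologs.partners_of(gid):
            if str(partner) not in graph.nodes:
                graph.add_node(
                    NodeRecord(
                        id=partner,
                        semantic_group=SemanticGroup.GENE,
                        preflabel=partner.local_id,
                        taxon=taxon,
                    )
                )
            # orthology is symmetric: store in lexicographic direction so
            # repeated expansion from either side dedups to one statement
            a, b = sorted((gid, partner), key=str)
            graph.add_edge(
                EdgeRecord(
                    subject=a,
                    property_id=UNMAPPED_RELATION_ID,
                    object=b,
                    property_label=ORTHOLOGY_LABEL,
                    reference_supporting_text="ortholog expansion",
                )
            )
            if str(partner) not in before:
                new_partners.append(partner)
                before.add(str(partner))
    for partner in new_partners:
        for phenotype, ref in orthologs.phenotypes_of(partner):
            if str(phenotype) not in graph.nodes:
                graph.add_node(
                    NodeRecord(
                        id=phenotype,
                        semantic_group=SemanticGroup.DISO,
                        preflabel=phenotype.local_id,
                    )
                )
            graph.add_edge(
                EdgeRecord(
                    subject=partner,
                    property_id=UNMAPPED_RELATION_ID,
                    object=phenotype,
                    property_label=HAS_PHENOTYPE,
                    reference_uri=[ref] if ref else [],
                    reference_supporting_text="ortholog phenotype",
                )
            )
    return graph


def passes_expression_filter(
    row: ExpressionRow,
    fold_change_min: float = DEFAULT_FOLD_CHANGE_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    log2_fold_change: bool = False,
) -> bool:
    """Strict differential-expression filter: |FC| > min AND FDR < max.

    Both inequalities are strict, so boundary rows (|FC| exactly at the
    threshold, FDR exactly at the cutoff) are excluded.  With
    ``log2_fold_change`` the input is interpreted on the log2 scale and
    compared against ``log2(fold_change_min)``.
    """
    threshold = (
        math.log2(fold_change_min) if log2_fold_change else fold_change_min
    )
    return abs(row.fold_change) > threshold and row.fdr < fdr_max


def build_expression_edges(
    rows: Sequence[ExpressionRow],
    source_gene: Curie,
    fold_change_min: float = DEFAULT_FOLD_CHANGE_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    log2_fold_change: bool = False,
) -> list[EdgeRecord]:
    """Link a perturbed gene to each differentially expressed gene.

    One "interacts with" edge per row passing the strict filter; the
    supporting text records the row's fold change and FDR so the evidence
    stays inspectable on the edge.
    """
    edges: list[EdgeRecord] = []
    for row in rows:
        if not passes_expression_filter(
            row, fold_change_min, fdr_max, log2_fold_change
        ):
            continue
        edges.append(
            EdgeRecord(
                subject=source_gene,
                property_id=UNMAPPED_RELATION_ID,
                object=as_curie(row.gene),
                property_label=INTERACTS_WITH,
                reference_supporting_text=(
                    f"differential expression: fold change "
                    f"{row.fold_change:g}, FDR {row.fdr:g}"
                ),
            )
        )
    return edges


def build_regulon_edges(
    regulons: Sequence[RegulonSet],
) -> list[EdgeRecord]:
    """Convert TF regulons into TF -> target regulatory edges."""
    edges: list[EdgeRecord] = []
    for reg in regulons:
        tf = as_curie(reg.regulator)
        for target in reg.targets:
            edges.append(
                EdgeRecord(
                    subject=tf,
                    property_id=UNMAPPED_RELATION_ID,
                    object=as_curie(target),
                    property_label=REGULATES,
                    reference_supporting_text=(
                        f"TF-target regulon ({reg.source_tag})"
                        if reg.source_tag
                        else "TF-target regulon"
                    ),
                )
            )
    return edges


# ---------------------------------------------------------------------------


def assemble_review(
    config: ReviewConfig,
) -> tuple[KnowledgeGraph, dict]:
    """Run the full assembly pipeline and return (graph, run manifest).

    Stage order: ingest -> relation/gene normalization -> seed
    neighborhood expansion -> ortholog expansion -> expression edges ->
    merge -> disease linking -> annotation.  The manifest records source
    paths and row counts, normalization tallies, the final graph summary
    and an echo of the configuration.
    """
    manifest: dict[str, Any] = {
        "config": {
            "seeds": [str(s) for s in config.seeds],
            "hops": config.hops,
            "fold_change_min": config.fold_change_min,
            "fdr_max": config.fdr_max,
            "log2_fold_change": config.log2_fold_change,
        },
        "sources": [],
        "normalization": {},
    }
    for decl in config.sources:
        if not os.path.exists(decl.path):
            raise InputError(f"declared source file not found: {decl.path}")
    for path in (
        config.gene_xref,
        config.disease_xref,
        config.relation_map,
        config.annotations,
    ):
        if path is not None and not os.path.exists(path):
            raise InputError(f"declared input file not found: {path}")

    relation_map = (
        read_relation_map(config.relation_map)
        if config.relation_map
        else {}
    )
    gene_xref = (
        read_xref_table(config.gene_xref) if config.gene_xref else None
    )

    networks: list[KnowledgeGraph] = []
    ortholog_tables: list[OrthologTable] = []
    expression_edge_count = 0
    for decl in config.sources:
        entry = {"path": decl.path, "kind": decl.kind}
        if decl.kind == "edges":
            edges = read_edge_table(
                decl.path, column_map=decl.options.get("column_map")
            )
            nodes = (
                read_node_table(decl.options["nodes"])
                if decl.options.get("nodes")
                else []
            )
            entry["rows"] = len(edges)
            networks.append(_normalized_network(
                edges, nodes, relation_map, gene_xref, manifest, decl.path
            ))
        elif decl.kind == "nodes":
            nodes = read_node_table(decl.path)
            entry["rows"] = len(nodes)
            networks.append(network_from([], nodes))
        elif decl.kind == "gmt":
            regs = read_gmt_regulons(
                decl.path, source_tag=decl.options.get("source_tag", "")
            )
            edges = build_regulon_edges(regs)
            entry["rows"] = len(regs)
            networks.append(_normalized_network(
                edges, [], relation_map, gene_xref, manifest, decl.path
            ))
        elif decl.kind == "expression":
            rows = read_expression_table(
                decl.path, column_map=decl.options.get("column_map")
            )
            source_gene = decl.options.get("source_gene")
            if source_gene is None:
                source_gene = config.expression_source_gene
            else:
                source_gene = parse_curie(source_gene)
            if source_gene is None:
                raise ConfigurationError(
                    f"expression source {decl.path}: no source_gene declared"
                )
            edges = build_expression_edges(
                rows,
                source_gene,
                config.fold_change_min,
                config.fdr_max,
                config.log2_fold_change,
            )
            entry["rows"] = len(rows)
            entry["edges_passing_filter"] = len(edges)
            expression_edge_count += len(edges)
            networks.append(_normalized_network(
                edges, [], relation_map, gene_xref, manifest, decl.path
            ))
        elif decl.kind == "orthologs":
            table = read_ortholog_table(
                decl.path, decl.options.get("path_phenotypes")
            )
            entry["rows"] = len(table.pairs)
            ortholog_tables.append(table)
        else:
            raise ConfigurationError(
                f"unknown source kind {decl.kind!r} for {decl.path}"
            )
        manifest["sources"].append(entry)

    graph = merge_networks(networks)

    if config.hops is not None:
        graph = neighborhood_expansion(graph, config.seeds, config.hops)
    for table in ortholog_tables:
        graph = expand_orthologs(graph, table)
    if config.disease_xref:
        graph = link_disease_ids(graph, read_xref_table(config.disease_xref))
    if config.annotations:
        ann_nodes = read_node_table(config.annotations)
        graph = annotate_nodes(
            graph, {str(n.id): n for n in ann_nodes}
        )
    else:
        graph = annotate_nodes(graph, {})

    if graph.n_nodes == 0:
        raise ValidationError("assembled review graph is empty")

    manifest["expression_edges"] = expression_edge_count
    manifest["graph_summary"] = graph_summary(graph)
    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    return graph, manifest


def _normalized_network(
    edges: list[EdgeRecord],
    nodes: list[NodeRecord],
    relation_map: dict,
    gene_xref,
    manifest: dict,
    source_path: str,
) -> KnowledgeGraph:
    if relation_map:
        edges, rel_report = map_relation_semantics(edges, relation_map)
        manifest["normalization"].setdefault("relations", {})[
            source_path
        ] = {
            "mapped": rel_report.rewritten,
            "unmapped": rel_report.unmapped,
            "unmapped_labels": rel_report.unmapped_labels,
        }
    if gene_xref is not None:
        edges, nodes, report = normalize_gene_ids(edges, nodes, gene_xref)
        manifest["normalization"].setdefault("genes", {})[source_path] = {
            "rewritten": report.rewritten,
            "unmapped": report.unmapped,
            "ambiguous": report.ambiguous,
        }
    return network_from(edges, nodes)


def write_manifest(manifest: dict, path: str | os.PathLike) -> None:
    os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
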