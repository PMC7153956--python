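"""Identifier and relation-semantics normalization.

Sources identify the same concepts under different vocabularies.  Two
asymmetric strategies are used, mirroring common practice in biomedical
graph integration:

* **Genes are rewritten** onto the preferred namespace (HGNC for human
  genes) using a cross-reference map — edge endpoints and node records
  change identifier.
* **Diseases are linked**, not rewritten: a ``skos:exactMatch`` edge is
  added from the original disease identifier to its MONDO counterpart,
  preserving the source identifier and its provenance.

Relation labels are mapped onto ontology relation identifiers (RO/SKOS
terms) via a curated two-way table; unmapped labels receive the sentinel
``BKR:unmapped`` and are reported rather than dropped.

All operations here are total and idempotent: problems are counted and
reported in a :class:`NormalizationReport`, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datamodel import (
    Curie,
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
    SemanticGroup,
    merge_node_into,
)
from .ingest import XrefMap

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationReport",
    "normalize_gene_ids",
    "link_disease_ids",
    "map_relation_semantics",
    "annotate_nodes",
    "EXACT_MATCH_ID",
    "EXACT_MATCH_URI",
    "UNMAPPED_RELATION_ID",
]

EXACT_MATCH_ID = Curie("skos", "exactMatch")
EXACT_MATCH_URI = "http://www.w3.org/2004/02/skos/core#exactMatch"
UNMAPPED_RELATION_ID = Curie("BKR", "unmapped")


@dataclass
class NormalizationReport:
    """Book-keeping for one normalization pass.

    ``rewritten + unmapped + ambiguous`` equals the number of identifiers
    considered; ambiguous cases list the alternatives so a curator can
    inspect the automatic tie-break.
    """

    rewritten: int = 0
    unmapped: int = 0
    ambiguous: int = 0
    ambiguous_cases: list[tuple[str, str, list[str]]] = field(
        default_factory=list
    )
    unmapped_labels: list[str] = field(default_factory=list)

    @property
    def considered(self) -> int:
        return self.rewritten + self.unmapped + self.ambiguous


def _choose_target(candidates: list[Curie]) -> Curie:
    # deterministic tie-break: lexicographically smallest serialization
    return min(candidates, key=str)


def normalize_gene_ids(
    edges: list[EdgeRecord],
    nodes: list[NodeRecord],
    xref: XrefMap,
) -> tuple[list[EdgeRecord], list[NodeRecord], NormalizationReport]:
    """Rewrite gene identifiers onto the preferred namespace.

    An identifier is *considered* when it belongs to a GENE-group node or
    appears in the cross-reference map.  Mappable identifiers are
    rewritten consistently in node records and edge endpoints; ambiguity
    (multiple candidates) is resolved to the lexicographically smallest
    serialization and reported; identifiers without a mapping are left
    unchanged and counted.  Edge count is preserved exactly.
    """
    report = NormalizationReport()
    gene_ids = {
        str(n.id) for n in nodes if n.semantic_group is SemanticGroup.GENE
    }
    considered: dict[str, None] = {}
    for n in nodes:
        if str(n.id) in gene_ids or str(n.id) in xref:
            considered.setdefault(str(n.id), None)
    for e in edges:
        for endpoint in (e.subject, e.object):
            key = str(endpoint)
            if key in gene_ids or key in xref:
                considered.setdefault(key, None)

    rewrite: dict[str, Curie] = {}
    for original in considered:
        candidates = xref.candidates(original)
        if not candidates:
            report.unmapped += 1
            continue
        chosen = _choose_target(candidates)
        rewrite[original] = chosen
        if len(candidates) > 1:
            report.ambiguous += 1
            report.ambiguous_cases.append(
                (
                    original,
                    str(chosen),
                    sorted(str(c) for c in candidates),
                )
            )
        else:
            report.rewritten += 1

    new_nodes: list[NodeRecord] = []
    for n in nodes:
        n = n.copy()
        target = rewrite.get(str(n.id))
        if target is not None:
            n.id = target
        new_nodes.append(n)
    new_edges: list[EdgeRecord] = []
    for e in edges:
        e = e.copy()
        e.subject = rewrite.get(str(e.subject), e.subject)
        e.object = rewrite.get(str(e.object), e.object)
        new_edges.append(e)
    return new_edges, new_nodes, report


def link_disease_ids(
    graph: KnowledgeGraph, xref: XrefMap
) -> KnowledgeGraph:
    """Link disease/phenotype nodes to MONDO via ``skos:exactMatch`` edges.

    Original identifiers are preserved; for each mapped DISO node one
    identity edge and (if new) one stub MONDO node are added.  With
    several candidates the lexicographically smallest is linked.
    Idempotent: statement deduplication absorbs repeated application.
    """
    graph = graph.copy()
    diso = [
        n
        for n in list(graph.nodes.values())
        if n.semantic_group is SemanticGroup.DISO
    ]
    for node in diso:
        candidates = xref.candidates(node.id)
        if not candidates:
            continue
        target = _choose_target(candidates)
        if str(target) == str(node.id):
            continue
        graph.add_node(
            NodeRecord(
                id=target,
                semantic_group=SemanticGroup.DISO,
                preflabel=target.local_id,
            )
        )
        graph.add_edge(
            EdgeRecord(
                subject=node.id,
                property_id=EXACT_MATCH_ID,
                object=target,
                property_label="exact match",
                property_uri=EXACT_MATCH_URI,
                reference_supporting_text="id-normalization",
            )
        )
    return graph


def map_relation_semantics(
    edges: list[EdgeRecord],
    relation_map: dict[str, tuple[Curie, str]],
) -> tuple[list[EdgeRecord], NormalizationReport]:
    """Fill relation identifiers/URIs from a curated label map.

    Edges whose ``property_label`` has a map entry get ``property_id`` and
    ``property_uri`` set; labels without an entry keep a sentinel
    ``BKR:unmapped`` identifier and are listed in the report.
    """
    report = NormalizationReport()
    seen_unmapped: dict[str, None] = {}
    out: list[EdgeRecord] = []
    for e in edges:
        e = e.copy()
        entry = relation_map.get(e.property_label)
        if entry is not None:
            e.property_id, uri = entry
            if uri:
                e.property_uri = uri
            report.rewritten += 1
        else:
            # unmapped label: keep it, stamped with the sentinel id unless
            # the source already supplied a concrete relation identifier
            # (curated ids are never clobbered)
            seen_unmapped.setdefault(e.property_label, None)
            report.unmapped += 1
        out.append(e)
    report.unmapped_labels = list(seen_unmapped)
    return out, report


def annotate_nodes(
    graph: KnowledgeGraph,
    annotations: dict[str, NodeRecord],
) -> KnowledgeGraph:
    """Fill node annotation from a table keyed by node id.

    Only empty fields are filled — curated values are never overwritten.
    UNKNOWN stubs are upgraded when the table supplies a semantic group.
    Nodes absent from the table keep (or receive) the fallback preflabel,
    the bare local id, so no node ends up unlabelled.
    """
    graph = graph.copy()
    for key, node in graph.nodes.items():
        ann = annotations.get(key)
        if ann is not None:
            merge_node_into(node, ann)
        if not node.preflabel:
            node.preflabel = node.id.local_id
    return graph
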