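"""Core types for structured-review knowledge graphs.

A structured review represents biomedical knowledge as a typed, directed
graph: nodes are concepts identified by compact identifiers (CURIEs, e.g.
``HGNC:17646``) carrying a coarse semantic group, and edges are provenanced
statements (subject, relation, object) carrying the supporting sentence and
reference URIs that let a reader trace each assertion back to its source.

The :class:`KnowledgeGraph` container deduplicates statements on their
(subject, relation, object) key, merging provenance from repeated
assertions, so that the same fact collected from several sources appears
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional

from .errors import MalformedIdentifierError, ValidationError

__all__ = [
    "Curie",
    "SemanticGroup",
    "NodeRecord",
    "EdgeRecord",
    "KnowledgeGraph",
    "parse_curie",
    "statement_key",
    "graph_summary",
    "as_curie",
]


@dataclass(frozen=True, order=True)
class Curie:
    """Compact identifier: ``prefix:local_id`` (e.g. ``MONDO:0000001``)."""

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix or ":" in self.prefix:
            raise MalformedIdentifierError(
                f"invalid CURIE prefix {self.prefix!r}"
            )
        if not self.local_id:
            raise MalformedIdentifierError(
                f"empty local id for prefix {self.prefix!r}"
            )

    def __str__(self) -> str:
        return f"{self.prefix}:{self.local_id}"


def parse_curie(text: str) -> Curie:
    """Parse ``prefix:local_id``, splitting on the first colon.

    Raises :class:`MalformedIdentifierError` when no colon is present or
    either part is empty; the message names the offending text.
    """
    if not isinstance(text, str) or not text:
        raise MalformedIdentifierError(f"malformed identifier: {text!r}")
    prefix, sep, local_id = text.partition(":")
    if not sep or not prefix or not local_id:
        raise MalformedIdentifierError(f"malformed identifier: {text!r}")
    return Curie(prefix, local_id)


#: Namespace used when a source supplies a bare symbol instead of a CURIE.
SYMBOL_PREFIX = "SYMBOL"


def as_curie(text: str | Curie, default_prefix: str = SYMBOL_PREFIX) -> Curie:
    """Coerce a string to a :class:`Curie`.

    Bare symbols (no colon) are wrapped in *default_prefix* so that edge
    endpoint invariants hold for sources (GMT regulons, expression tables)
    that identify genes by symbol.
    """
    if isinstance(text, Curie):
        return text
    if ":" in text:
        return parse_curie(text)
    if not text:
        raise MalformedIdentifierError("empty identifier")
    return Curie(default_prefix, text)


class SemanticGroup(str, Enum):
    """Coarse node type; DISO covers both diseases and phenotypes."""

    GENE = "GENE"
    DISO = "DISO"
    PATHWAY = "PATHWAY"
    ANATOMY = "ANATOMY"
    VARIANT = "VARIANT"
    GENOTYPE = "GENOTYPE"
    CHEMICAL = "CHEMICAL"
    ORGANISM = "ORGANISM"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass
class NodeRecord:
    """A typed biomedical concept with human-readable annotation."""

    id: Curie
    semantic_group: SemanticGroup = SemanticGroup.UNKNOWN
    preflabel: str = ""
    name: str = ""
    synonyms: list[str] = field(default_factory=list)
    description: str = ""
    taxon: str = ""

    def copy(self) -> "NodeRecord":
        return replace(self, synonyms=list(self.synonyms))


@dataclass
class EdgeRecord:
    """A provenanced statement: subject --property--> object.

    ``reference_uri`` lists the sources backing the statement;
    ``reference_supporting_text`` holds the curated sentence(s).
    """

    subject: Curie
    property_id: Curie
    object: Curie
    property_label: str = ""
    property_uri: str = ""
    reference_uri: list[str] = field(default_factory=list)
    reference_supporting_text: str = ""
    reference_date: str = ""

    def __post_init__(self) -> None:
        for fname in ("subject", "property_id", "object"):
            if not isinstance(getattr(self, fname), Curie):
                raise ValidationError(
                    f"edge field {fname!r} must be a Curie, "
                    f"got {getattr(self, fname)!r}"
                )
        # provenance lists are kept deduplicated, first-seen order
        self.reference_uri = _dedup(self.reference_uri)

    def copy(self) -> "EdgeRecord":
        return replace(self, reference_uri=list(self.reference_uri))


def _dedup(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for it in items:
        if it:
            seen.setdefault(it, None)
    return list(seen)


def statement_key(edge: EdgeRecord) -> str:
    """Deterministic identity of a statement: ``subject|property|object``.

    Provenance fields are deliberately excluded so that the same fact
    asserted by several sources collapses to a single edge.
    """
    return f"{edge.subject}|{edge.property_id}|{edge.object}"


TEXT_JOIN = " | "


class KnowledgeGraph:
    """Deduplicated node/edge store.

    Statements are keyed on (subject, property_id, object); re-adding an
    existing statement merges provenance (reference-URI union, distinct
    supporting texts joined with ``" | "`` in first-seen order) instead of
    duplicating the edge.  Edge endpoints without a node record are
    auto-stubbed as UNKNOWN-group nodes so the endpoint invariant always
    holds; annotation later upgrades stubs.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, NodeRecord] = {}
        self._edges: dict[str, EdgeRecord] = {}

    # -- nodes -----------------------------------------------------------
    def add_node(self, node: NodeRecord) -> NodeRecord:
        """Insert or merge a node record (field-wise, first non-empty wins)."""
        key = str(node.id)
        existing = self.nodes.get(key)
        if existing is None:
            self.nodes[key] = node.copy()
            return self.nodes[key]
        merge_node_into(existing, node)
        return existing

    def get_node(self, node_id: Curie | str) -> Optional[NodeRecord]:
        return self.nodes.get(str(node_id))

    def _ensure_endpoint(self, node_id: Curie) -> None:
        key = str(node_id)
        if key not in self.nodes:
            self.nodes[key] = NodeRecord(
                id=node_id,
                semantic_group=SemanticGroup.UNKNOWN,
                preflabel=node_id.local_id,
            )

    # -- edges -----------------------------------------------------------
    def add_edge(self, edge: EdgeRecord) -> EdgeRecord:
        """Insert a statement, merging provenance on duplicate keys."""
        if not isinstance(edge, EdgeRecord):
            raise ValidationError(f"not an EdgeRecord: {edge!r}")
        key = statement_key(edge)
        existing = self._edges.get(key)
        if existing is None:
            self._edges[key] = edge.copy()
            self._ensure_endpoint(edge.subject)
            self._ensure_endpoint(edge.object)
            return self._edges[key]
        existing.reference_uri = _dedup(
            existing.reference_uri + edge.reference_uri
        )
        texts = [
            t
            for t in existing.reference_supporting_text.split(TEXT_JOIN)
            if t
        ]
        for t in edge.reference_supporting_text.split(TEXT_JOIN):
            if t and t not in texts:
                texts.append(t)
        existing.reference_supporting_text = TEXT_JOIN.join(texts)
        if not existing.property_label:
            existing.property_label = edge.property_label
        if not existing.property_uri:
            existing.property_uri = edge.property_uri
        if not existing.reference_date:
            existing.reference_date = edge.reference_date
        return existing

    def add_edges(self, edges: Iterable[EdgeRecord]) -> None:
        for e in edges:
            self.add_edge(e)

    @property
    def edges(self) -> list[EdgeRecord]:
        return list(self._edges.values())

    def get_edge(self, key: str) -> Optional[EdgeRecord]:
        return self._edges.get(key)

    def iter_edges(self) -> Iterator[EdgeRecord]:
        return iter(self._edges.values())

    # -- container protocol ---------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node_id: Curie | str) -> bool:
        return str(node_id) in self.nodes

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph()
        for node in self.nodes.values():
            g.nodes[str(node.id)] = node.copy()
        for key, edge in self._edges.items():
            g._edges[key] = edge.copy()
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            {k: _node_tuple(v) for k, v in self.nodes.items()}
            == {k: _node_tuple(v) for k, v in other.nodes.items()}
            and {k: _edge_tuple(v) for k, v in self._edges.items()}
            == {k: _edge_tuple(v) for k, v in other._edges.items()}
        )

    def __repr__(self) -> str:
        return (
            f"<KnowledgeGraph {self.n_nodes} nodes, {self.n_edges} edges>"
        )


def _node_tuple(n: NodeRecord):
    return (
        str(n.id),
        n.semantic_group.value,
        n.preflabel,
        n.name,
        tuple(n.synonyms),
        n.description,
        n.taxon,
    )


def _edge_tuple(e: EdgeRecord):
    return (
        str(e.subject),
        str(e.property_id),
        str(e.object),
        e.property_label,
        e.property_uri,
        tuple(e.reference_uri),
        e.reference_supporting_text,
        e.reference_date,
    )


def merge_node_into(target: NodeRecord, source: NodeRecord) -> list[str]:
    """Merge *source* annotation into *target*; first non-empty wins.

    Returns the names of fields where both sides held conflicting
    non-empty values (target kept).
    """
    conflicts: list[str] = []
    if target.semantic_group is SemanticGroup.UNKNOWN:
        target.semantic_group = source.semantic_group
    elif (
        source.semantic_group is not SemanticGroup.UNKNOWN
        and source.semantic_group is not target.semantic_group
    ):
        conflicts.append("semantic_group")
    for fname in ("preflabel", "name", "description", "taxon"):
        mine, theirs = getattr(target, fname), getattr(source, fname)
        if not mine and theirs:
            setattr(target, fname, theirs)
        elif mine and theirs and mine != theirs:
            # stub preflabels (bare local id) always yield to annotation
            if fname == "preflabel" and mine == target.id.local_id:
                setattr(target, fname, theirs)
            else:
                conflicts.append(fname)
    target.synonyms = _dedup(target.synonyms + source.synonyms)
    return conflicts


def graph_summary(graph: KnowledgeGraph) -> dict:
    """Summary statistics: totals plus per-group and per-relation counts.

    Breakdown orderings are deterministic: descending count, ties broken
    lexicographically.
    """
    by_group: dict[str, int] = {}
    for node in graph.nodes.values():
        g = node.semantic_group.value
        by_group[g] = by_group.get(g, 0) + 1
    by_label: dict[str, int] = {}
    for edge in graph.iter_edges():
        lbl = edge.property_label or str(edge.property_id)
        by_label[lbl] = by_label.get(lbl, 0) + 1

    def _ordered(d: dict[str, int]) -> dict[str, int]:
        return dict(sorted(d.items(), key=lambda kv: (-kv[1], kv[0])))

    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "nodes_by_group": _ordered(by_group),
        "edges_by_label": _ordered(by_label),
        "n_relation_types": len(by_label),
    }
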