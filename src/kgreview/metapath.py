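"""Typed path templates and enumeration: the hypothesis-generation engine.

A *metapath template* is an alternating sequence of node and edge
constraints — for example gene → (regulates) → gene → (orthology) → gene —
with optionally anchored endpoints.  Enumerating all simple paths of a
knowledge graph that satisfy such a template produces a list of candidate
mechanistic hypotheses: each matched path is a concrete chain of
provenanced statements connecting the anchors.  A positional frequency
summary over the matched paths then surfaces the recurring intermediate
concepts (the most common genes, transcription factors, phenotypes, ...).

Semantics:

* Paths are **simple** (no repeated node), preventing degenerate cycles in
  hypothesis lists.
* Edge direction constraints are interpreted against storage direction:
  ``forward`` requires the stored edge to point from position i to i+1,
  ``reverse`` the opposite, ``any`` (the default) accepts either.
* Identifier-identity edges (``skos:exactMatch``) never match wildcard
  edge constraints; a template must name them explicitly to traverse
  them.  Identity links are not mechanistic hypotheses.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .datamodel import (
    Curie,
    EdgeRecord,
    KnowledgeGraph,
    SemanticGroup,
    parse_curie,
    statement_key,
)
from .errors import ValidationError
from .normalize import EXACT_MATCH_ID

__all__ = [
    "NodeConstraint",
    "EdgeConstraint",
    "MetapathTemplate",
    "PathResult",
    "PathList",
    "PathSummary",
    "compile_template",
    "load_template",
    "enumerate_paths",
    "summarize_paths",
]

FORWARD = "forward"
REVERSE = "reverse"
ANY = "any"

_EXACT_MATCH = str(EXACT_MATCH_ID)


@dataclass(frozen=True)
class NodeConstraint:
    """Constraint on one path position.

    ``fixed_id`` anchors the position to a single concept and overrides
    all other fields; otherwise any combination of semantic groups, taxon
    and identifier prefixes may be required.  All fields empty means the
    wildcard constraint.
    """

    fixed_id: Optional[Curie] = None
    groups: Optional[frozenset[SemanticGroup]] = None
    taxon: Optional[str] = None
    prefixes: Optional[frozenset[str]] = None

    @property
    def anchored(self) -> bool:
        return self.fixed_id is not None

    def matches(self, node) -> bool:
        if self.fixed_id is not None:
            return str(node.id) == str(self.fixed_id)
        if self.groups is not None and node.semantic_group not in self.groups:
            return False
        if self.taxon is not None and node.taxon != self.taxon:
            return False
        if self.prefixes is not None and node.id.prefix not in self.prefixes:
            return False
        return True


@dataclass(frozen=True)
class EdgeConstraint:
    """Constraint on one path step.

    Either relation identifiers or labels (or both) may be restricted;
    ``direction`` defaults to ``any``.
    """

    property_ids: Optional[frozenset[str]] = None
    property_labels: Optional[frozenset[str]] = None
    direction: str = ANY

    def __post_init__(self) -> None:
        if self.direction not in (FORWARD, REVERSE, ANY):
            raise ValidationError(
                f"unknown direction {self.direction!r}"
            )
        for f in (self.property_ids, self.property_labels):
            if f is not None and not f:
                raise ValidationError(
                    "empty constraint set; omit the field instead"
                )

    def allows_direction(self, travelled: str) -> bool:
        return self.direction == ANY or self.direction == travelled

    def matches_edge(self, edge: EdgeRecord) -> bool:
        pid = str(edge.property_id)
        explicit = (
            self.property_ids is not None or self.property_labels is not None
        )
        if pid == _EXACT_MATCH and not explicit:
            return False  # identity links never match wildcards
        if self.property_ids is not None and pid not in self.property_ids:
            return False
        if (
            self.property_labels is not None
            and edge.property_label not in self.property_labels
        ):
            return False
        return True


@dataclass(frozen=True)
class MetapathTemplate:
    """Alternating node/edge constraints; L edges and L+1 nodes."""

    node_constraints: tuple[NodeConstraint, ...]
    edge_constraints: tuple[EdgeConstraint, ...]

    def __post_init__(self) -> None:
        if len(self.edge_constraints) < 1:
            raise ValidationError("template must have at least one edge")
        if len(self.node_constraints) != len(self.edge_constraints) + 1:
            raise ValidationError(
                f"length mismatch: {len(self.node_constraints)} node "
                f"constraints require "
                f"{len(self.node_constraints) - 1} edge constraints, "
                f"got {len(self.edge_constraints)}"
            )

    @property
    def length(self) -> int:
        return len(self.edge_constraints)

    def reversed(self) -> "MetapathTemplate":
        flip = {FORWARD: REVERSE, REVERSE: FORWARD, ANY: ANY}
        return MetapathTemplate(
            node_constraints=tuple(reversed(self.node_constraints)),
            edge_constraints=tuple(
                EdgeConstraint(
                    property_ids=c.property_ids,
                    property_labels=c.property_labels,
                    direction=flip[c.direction],
                )
                for c in reversed(self.edge_constraints)
            ),
        )


@dataclass(frozen=True, order=True)
class PathResult:
    """One matched path: node ids, statement keys and travel directions."""

    nodes: tuple[str, ...]
    edges: tuple[str, ...]
    directions: tuple[str, ...]

    def reversed(self) -> "PathResult":
        flip = {FORWARD: REVERSE, REVERSE: FORWARD}
        return PathResult(
            nodes=tuple(reversed(self.nodes)),
            edges=tuple(reversed(self.edges)),
            directions=tuple(flip[d] for d in reversed(self.directions)),
        )


class PathList(list):
    """Result list for a path query; ``truncated`` marks a hit limit."""

    truncated: bool = False


# ---------------------------------------------------------------------------
# template compilation


def compile_template(spec: dict | str) -> MetapathTemplate:
    """Compile a template from its JSON document form.

    The document has a ``nodes`` array (entries with optional ``id``,
    ``groups``, ``taxon``, ``prefixes``; an empty object is the wildcard)
    and an ``edges`` array (entries with optional ``ids``, ``labels`` and
    ``direction``), with ``len(edges) == len(nodes) - 1``.
    """
    if isinstance(spec, str):
        spec = json.loads(spec)
    if not isinstance(spec, dict):
        raise ValidationError("template document must be a JSON object")
    for key in ("nodes", "edges"):
        if key not in spec or not isinstance(spec[key], list):
            raise ValidationError(f"template needs a {key!r} array")
    node_constraints = []
    for i, entry in enumerate(spec["nodes"]):
        if not isinstance(entry, dict):
            raise ValidationError(f"nodes[{i}] must be an object")
        unknown = set(entry) - {"id", "groups", "taxon", "prefixes"}
        if unknown:
            raise ValidationError(
                f"nodes[{i}]: unknown fields {sorted(unknown)}"
            )
        groups = None
        if "groups" in entry:
            if not entry["groups"]:
                raise ValidationError(
                    f"nodes[{i}]: empty groups list; omit the field"
                )
            try:
                groups = frozenset(
                    SemanticGroup(g) for g in entry["groups"]
                )
            except ValueError as exc:
                raise ValidationError(f"nodes[{i}]: {exc}") from exc
        prefixes = None
        if "prefixes" in entry:
            if not entry["prefixes"]:
                raise ValidationError(
                    f"nodes[{i}]: empty prefixes list; omit the field"
                )
            prefixes = frozenset(entry["prefixes"])
        node_constraints.append(
            NodeConstraint(
                fixed_id=(
                    parse_curie(entry["id"]) if entry.get("id") else None
                ),
                groups=groups,
                taxon=entry.get("taxon"),
                prefixes=prefixes,
            )
        )
    edge_constraints = []
    for i, entry in enumerate(spec["edges"]):
        if not isinstance(entry, dict):
            raise ValidationError(f"edges[{i}] must be an object")
        unknown = set(entry) - {"ids", "labels", "direction"}
        if unknown:
            raise ValidationError(
                f"edges[{i}]: unknown fields {sorted(unknown)}"
            )
        ids = None
        if "ids" in entry:
            if not entry["ids"]:
                raise ValidationError(
                    f"edges[{i}]: empty ids list; omit the field"
                )
            ids = frozenset(str(parse_curie(x)) for x in entry["ids"])
        labels = None
        if "labels" in entry:
            if not entry["labels"]:
                raise ValidationError(
                    f"edges[{i}]: empty labels list; omit the field"
                )
            labels = frozenset(entry["labels"])
        edge_constraints.append(
            EdgeConstraint(
                property_ids=ids,
                property_labels=labels,
                direction=entry.get("direction", ANY),
            )
        )
    return MetapathTemplate(
        node_constraints=tuple(node_constraints),
        edge_constraints=tuple(edge_constraints),
    )


def load_template(path: str | os.PathLike) -> MetapathTemplate:
    """Load and compile a template JSON file."""
    with open(path, encoding="utf-8") as fh:
        return compile_template(json.load(fh))


# ---------------------------------------------------------------------------
# enumeration


def _adjacency(graph: KnowledgeGraph):
    out_idx: dict[str, list[EdgeRecord]] = {}
    in_idx: dict[str, list[EdgeRecord]] = {}
    for edge in graph.iter_edges():
        out_idx.setdefault(str(edge.subject), []).append(edge)
        in_idx.setdefault(str(edge.object), []).append(edge)
    return out_idx, in_idx


def enumerate_paths(
    graph: KnowledgeGraph,
    template: MetapathTemplate,
    limit: Optional[int] = None,
) -> PathList:
    """All simple paths of the graph satisfying the template.

    Results are ordered lexicographically by node-id sequence (ties broken
    by statement-key sequence) so enumeration is deterministic.  When
    ``limit`` is given the list is truncated and flagged.

    The search is a constrained depth-first expansion from the anchored
    end (the template is traversed from whichever endpoint is anchored,
    which prunes the search on large graphs); any strategy must and does
    return exactly the set a brute-force simple-path enumeration with
    constraint filtering would.
    """
    flipped = (
        not template.node_constraints[0].anchored
        and template.node_constraints[-1].anchored
    )
    work = template.reversed() if flipped else template
    out_idx, in_idx = _adjacency(graph)

    results: list[PathResult] = []
    ncs, ecs = work.node_constraints, work.edge_constraints
    L = work.length

    first = ncs[0]
    if first.anchored:
        node = graph.get_node(first.fixed_id)
        starts = [str(first.fixed_id)] if node is not None else []
    else:
        starts = [
            key for key, node in graph.nodes.items() if first.matches(node)
        ]

    def extend(
        pos: int,
        nodes: tuple[str, ...],
        edges: tuple[str, ...],
        dirs: tuple[str, ...],
    ) -> None:
        if pos == L:
            results.append(
                PathResult(nodes=nodes, edges=edges, directions=dirs)
            )
            return
        ec = ecs[pos]
        nc = ncs[pos + 1]
        tail = nodes[-1]
        candidates: list[tuple[EdgeRecord, str, str]] = []
        if ec.allows_direction(FORWARD):
            for e in out_idx.get(tail, ()):
                candidates.append((e, str(e.object), FORWARD))
        if ec.allows_direction(REVERSE):
            for e in in_idx.get(tail, ()):
                candidates.append((e, str(e.subject), REVERSE))
        for e, nxt, travelled in candidates:
            if nxt in nodes:
                continue  # simple paths only
            if not ec.matches_edge(e):
                continue
            nxt_node = graph.nodes.get(nxt)
            if nxt_node is None or not nc.matches(nxt_node):
                continue
            extend(
                pos + 1,
                nodes + (nxt,),
                edges + (statement_key(e),),
                dirs + (travelled,),
            )

    for start in sorted(starts):
        extend(0, (start,), (), ())

    if flipped:
        results = [p.reversed() for p in results]
    results.sort(key=lambda p: (p.nodes, p.edges))
    out = PathList()
    if limit is not None and len(results) > limit:
        out.extend(results[:limit])
        out.truncated = True
    else:
        out.extend(results)
    return out


# ---------------------------------------------------------------------------
# summaries


@dataclass
class PathSummary:
    """Positional node-frequency table over a set of matched paths.

    Rows are (position, node id, semantic group, count), ordered by
    position, then descending count, then identifier.  Without a group
    filter, counts at each reported position sum to the number of paths.
    """

    n_paths: int
    rows: list[tuple[int, str, str, int]] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["position\tnode_id\tsemantic_group\tcount"]
        for pos, nid, group, count in self.rows:
            lines.append(f"{pos}\t{nid}\t{group}\t{count}")
        return "\n".join(lines) + "\n"


def summarize_paths(
    paths: Sequence[PathResult],
    graph: KnowledgeGraph,
    group_filter: Optional[SemanticGroup] = None,
    template: Optional[MetapathTemplate] = None,
) -> PathSummary:
    """Frequency of nodes at each intermediate path position.

    Anchored endpoint positions (known from *template* when given,
    otherwise endpoint positions where all paths agree on one node) are
    excluded — they are constants of the query, not findings.  An
    optional group filter restricts rows to one semantic group without
    changing the counts of the remaining rows.
    """
    summary = PathSummary(n_paths=len(paths))
    if not paths:
        return summary
    length = len(paths[0].nodes)
    for p in paths:
        if len(p.nodes) != length:
            raise ValidationError(
                "mixed-length path list cannot be summarized"
            )

    def _excluded(pos: int) -> bool:
        if pos not in (0, length - 1):
            return False
        if template is not None:
            return template.node_constraints[pos].anchored
        return len({p.nodes[pos] for p in paths}) == 1

    counts: dict[tuple[int, str], int] = {}
    for p in paths:
        for pos, nid in enumerate(p.nodes):
            if _excluded(pos):
                continue
            counts[(pos, nid)] = counts.get((pos, nid), 0) + 1
    rows = []
    for (pos, nid), count in counts.items():
        node = graph.get_node(nid)
        group = node.semantic_group.value if node else "UNKNOWN"
        if group_filter is not None and group != group_filter.value:
            continue
        rows.append((pos, nid, group, count))
    rows.sort(key=lambda r: (r[0], -r[3], r[1]))
    summary.rows = rows
    return summary


def paths_to_tsv(
    paths: Iterable[PathResult], graph: KnowledgeGraph
) -> str:
    """Render matched paths as TSV: node ids, edge labels, provenance."""
    lines = ["nodes\tedge_labels\treferences"]
    for p in paths:
        labels = []
        refs: list[str] = []
        for key in p.edges:
            edge = graph.get_edge(key)
            labels.append(edge.property_label if edge else "")
            if edge:
                refs.extend(edge.reference_uri)
        lines.append(
            "|".join(p.nodes)
            + "\t"
            + "|".join(labels)
            + "\t"
            + "|".join(dict.fromkeys(refs))
        )
    return "\n".join(lines) + "\n"
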