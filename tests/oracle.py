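"""Brute-force reference for template-matching path enumeration.

Exhaustively walks every simple path by trying, at each step, every edge
of the graph in both orientations, then filters by an independent
re-implementation of the constraint semantics.  Deliberately shares no
code with the engine's indexed, anchored search — this is the ground
truth it is validated against.
"""

from __future__ import annotations

from kgreview.datamodel import KnowledgeGraph
from kgreview.metapath import MetapathTemplate, PathResult


def _node_ok(nc, node) -> bool:
    if nc.fixed_id is not None:
        return str(node.id) == str(nc.fixed_id)
    if nc.groups is not None and node.semantic_group not in nc.groups:
        return False
    if nc.taxon is not None and node.taxon != nc.taxon:
        return False
    if nc.prefixes is not None and node.id.prefix not in nc.prefixes:
        return False
    return True


def _edge_ok(ec, edge, travelled: str) -> bool:
    if ec.direction not in ("any", travelled):
        return False
    pid = f"{edge.property_id}"
    wildcard = ec.property_ids is None and ec.property_labels is None
    if pid == "skos:exactMatch" and wildcard:
        return False  # identity links only match when named explicitly
    if ec.property_ids is not None and pid not in ec.property_ids:
        return False
    if (
        ec.property_labels is not None
        and edge.property_label not in ec.property_labels
    ):
        return False
    return True


def _key(e) -> str:
    return f"{e.subject}|{e.property_id}|{e.object}"


def oracle_paths(
    graph: KnowledgeGraph, template: MetapathTemplate
) -> set[PathResult]:
    """All constraint-satisfying simple paths, by exhaustive DFS."""
    L = len(template.edge_constraints)
    all_edges = list(graph.iter_edges())
    results: set[PathResult] = set()

    def rec(pos, nodes, edges, dirs):
        if pos == L:
            results.add(
                PathResult(tuple(nodes), tuple(edges), tuple(dirs))
            )
            return
        tail = nodes[-1]
        for e in all_edges:
            for travelled, frm, to in (
                ("forward", str(e.subject), str(e.object)),
                ("reverse", str(e.object), str(e.subject)),
            ):
                if frm != tail or to in nodes:
                    continue
                if not _edge_ok(template.edge_constraints[pos], e,
                                travelled):
                    continue
                if not _node_ok(
                    template.node_constraints[pos + 1], graph.nodes[to]
                ):
                    continue
                rec(
                    pos + 1,
                    nodes + [to],
                    edges + [_key(e)],
                    dirs + [travelled],
                )

    for nid, node in graph.nodes.items():
        if _node_ok(template.node_constraints[0], node):
            rec(0, [nid], [], [])
    return results
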