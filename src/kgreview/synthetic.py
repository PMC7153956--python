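"""Synthetic fixtures: multi-typed graphs, planted paths, expression tables.

Every stage of the review pipeline is testable offline against generated
data with known ground truth.  The generator emulates the *shape* of the
real inputs — a multi-typed graph with a handful of semantic groups and
named relation types, TF-regulon-like edges, and a differential-expression
table — not real biological content or degree distributions.

Ground truth is exact by construction: planted template instances use
fresh intermediate nodes so each instance is a distinct, countable match,
and generated expression tables place every row strictly on the intended
side of the significance filter (including exact-boundary rows, which the
strict filter must exclude).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .datamodel import (
    Curie,
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
    SemanticGroup,
    statement_key,
)
from .errors import ValidationError
from .ingest import ExpressionRow
from .metapath import (
    ANY,
    FORWARD,
    REVERSE,
    EdgeConstraint,
    MetapathTemplate,
    NodeConstraint,
    PathResult,
)

__all__ = [
    "RelationSpec",
    "SyntheticSpec",
    "GroundTruthManifest",
    "generate_graph",
    "plant_template_instances",
    "generate_expression_table",
    "write_expression_table",
    "random_spec",
    "random_template",
]


@dataclass(frozen=True)
class RelationSpec:
    """One synthetic relation type with typed endpoints and edge count."""

    label: str
    subject_group: SemanticGroup
    object_group: SemanticGroup
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError("relation edge count must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic graph; a fixed seed fixes the output."""

    node_counts: dict[SemanticGroup, int]
    relations: tuple[RelationSpec, ...]
    seed: int = 0
    taxa: dict[SemanticGroup, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, count in self.node_counts.items():
            if count < 0:
                raise ValidationError(
                    f"negative node count for {group}"
                )


@dataclass
class GroundTruthManifest:
    """What the generator knows to be true about its output."""

    planted_paths: list[PathResult] = field(default_factory=list)
    de_pass_indices: list[int] = field(default_factory=list)


def _node_id(group: SemanticGroup, i: int) -> Curie:
    return Curie(group.value, str(i + 1))


def _relation_id(label: str) -> Curie:
    return Curie("SYNR", label.replace(" ", "_"))


def generate_graph(
    spec: SyntheticSpec,
) -> tuple[KnowledgeGraph, GroundTruthManifest]:
    """Generate a typed graph with exact per-group and per-type counts.

    Edges of each relation type are drawn uniformly without replacement
    among type-compatible endpoint pairs (self-loops excluded), so no
    duplicate statements arise.  Deterministic for a fixed seed.
    """
    rng = random.Random(spec.seed)
    graph = KnowledgeGraph()
    ids: dict[SemanticGroup, list[Curie]] = {}
    for group in sorted(spec.node_counts, key=lambda g: g.value):
        count = spec.node_counts[group]
        ids[group] = [_node_id(group, i) for i in range(count)]
        for nid in ids[group]:
            graph.add_node(
                NodeRecord(
                    id=nid,
                    semantic_group=group,
                    preflabel=f"{group.value.lower()} {nid.local_id}",
                    taxon=spec.taxa.get(group, ""),
                )
            )
    for rel in spec.relations:
        subjects = ids.get(rel.subject_group, [])
        objects = ids.get(rel.object_group, [])
        pairs = [
            (s, o)
            for s in subjects
            for o in objects
            if str(s) != str(o)
        ]
        if rel.count > len(pairs):
            raise ValidationError(
                f"relation {rel.label!r}: requested {rel.count} edges "
                f"but only {len(pairs)} distinct statements possible"
            )
        for s, o in rng.sample(pairs, rel.count):
            graph.add_edge(
                EdgeRecord(
                    subject=s,
                    property_id=_relation_id(rel.label),
                    object=o,
                    property_label=rel.label,
                    property_uri=(
                        f"http://example.org/relation/"
                        f"{rel.label.replace(' ', '_')}"
                    ),
                    reference_uri=["http://example.org/ref/synthetic"],
                    reference_supporting_text="synthetic edge",
                )
            )
    return graph, GroundTruthManifest()


# ---------------------------------------------------------------------------
# planted template instances


def _satisfying_node(
    constraint: NodeConstraint, tag: str
) -> NodeRecord:
    """Fresh node record satisfying a (non-anchored) node constraint."""
    prefix = (
        sorted(constraint.prefixes)[0]
        if constraint.prefixes
        else "PLANT"
    )
    group = (
        sorted(constraint.groups, key=lambda g: g.value)[0]
        if constraint.groups
        else SemanticGroup.UNKNOWN
    )
    return NodeRecord(
        id=Curie(prefix, tag),
        semantic_group=group,
        preflabel=tag,
        taxon=constraint.taxon or "",
    )


def _satisfying_edge(
    constraint: EdgeConstraint, a: Curie, b: Curie
) -> tuple[EdgeRecord, str]:
    """Edge between a and b satisfying an edge constraint.

    Returns the record plus the direction travelled from a to b.
    """
    if constraint.property_labels:
        label = sorted(constraint.property_labels)[0]
    else:
        label = "planted relation"
    if constraint.property_ids:
        pid_text = sorted(constraint.property_ids)[0]
        prefix, _, local = pid_text.partition(":")
        pid = Curie(prefix, local)
    else:
        pid = _relation_id(label)
    if constraint.direction == REVERSE:
        subject, obj, travelled = b, a, REVERSE
    else:
        subject, obj, travelled = a, b, FORWARD
    return (
        EdgeRecord(
            subject=subject,
            property_id=pid,
            object=obj,
            property_label=label,
            reference_supporting_text="planted edge",
        ),
        travelled,
    )


def plant_template_instances(
    graph: KnowledgeGraph,
    template: MetapathTemplate,
    k: int,
    seed: int = 0,
) -> tuple[KnowledgeGraph, GroundTruthManifest]:
    """Add k disjoint chains, each satisfying the template.

    Intermediate (non-anchored) positions get fresh nodes, so every
    planted instance is a distinct guaranteed match; anchored positions
    reuse (or create) the anchor node, so all instances share the
    anchors.  Background edges may create further legitimate matches, so
    planted instances bound the match count from below.
    """
    if k < 0:
        raise ValidationError("number of planted instances must be >= 0")
    graph = graph.copy()
    manifest = GroundTruthManifest()
    for inst in range(k):
        node_ids: list[Curie] = []
        for pos, nc in enumerate(template.node_constraints):
            if nc.anchored:
                nid = nc.fixed_id
                if str(nid) not in graph.nodes:
                    group = (
                        sorted(nc.groups, key=lambda g: g.value)[0]
                        if nc.groups
                        else SemanticGroup.UNKNOWN
                    )
                    graph.add_node(
                        NodeRecord(
                            id=nid,
                            semantic_group=group,
                            preflabel=nid.local_id,
                            taxon=nc.taxon or "",
                        )
                    )
                node_ids.append(nid)
            else:
                node = _satisfying_node(nc, f"p{seed}_{inst}_{pos}")
                graph.add_node(node)
                node_ids.append(node.id)
        edge_keys: list[str] = []
        dirs: list[str] = []
        for pos, ec in enumerate(template.edge_constraints):
            edge, travelled = _satisfying_edge(
                ec, node_ids[pos], node_ids[pos + 1]
            )
            stored = graph.add_edge(edge)
            edge_keys.append(statement_key(stored))
            dirs.append(travelled)
        manifest.planted_paths.append(
            PathResult(
                nodes=tuple(str(n) for n in node_ids),
                edges=tuple(edge_keys),
                directions=tuple(dirs),
            )
        )
    return graph, manifest


# ---------------------------------------------------------------------------
# expression tables


def generate_expression_table(
    n: int,
    n_de: int,
    fold_change_min: float = 1.5,
    fdr_max: float = 0.05,
    seed: int = 0,
) -> tuple[list[ExpressionRow], GroundTruthManifest]:
    """Expression table with exactly *n_de* rows passing the strict filter.

    Passing rows are drawn strictly beyond both thresholds; failing rows
    violate at least one, and a share of them sit exactly on a boundary
    (|fold change| equal to the threshold, or FDR equal to the cutoff) to
    exercise the strictness of the inequalities.
    """
    if not (0 <= n_de <= n):
        raise ValidationError(f"need 0 <= n_de <= n, got {n_de}/{n}")
    rng = random.Random(seed)
    indices = list(range(n))
    rng.shuffle(indices)
    pass_set = set(indices[:n_de])
    rows: list[ExpressionRow] = []
    manifest = GroundTruthManifest(de_pass_indices=sorted(pass_set))
    for i in range(n):
        sign = rng.choice((-1.0, 1.0))
        if i in pass_set:
            fc = sign * rng.uniform(fold_change_min * 1.2,
                                    fold_change_min * 4)
            fdr = rng.uniform(0, fdr_max * 0.8)
        else:
            mode = rng.choice(("fc", "fdr", "both", "boundary"))
            if mode == "fc":
                fc = sign * rng.uniform(0.1, fold_change_min * 0.9)
                fdr = rng.uniform(0, fdr_max * 0.8)
            elif mode == "fdr":
                fc = sign * rng.uniform(fold_change_min * 1.2,
                                        fold_change_min * 4)
                fdr = rng.uniform(min(fdr_max * 1.2, 1.0), 1.0)
            elif mode == "both":
                fc = sign * rng.uniform(0.1, fold_change_min * 0.9)
                fdr = rng.uniform(min(fdr_max * 1.2, 1.0), 1.0)
            else:
                # exactly on a boundary: strict filter must exclude
                if rng.random() < 0.5:
                    fc = sign * fold_change_min
                    fdr = rng.uniform(0, fdr_max * 0.8)
                else:
                    fc = sign * rng.uniform(fold_change_min * 1.2,
                                            fold_change_min * 4)
                    fdr = fdr_max
        rows.append(
            ExpressionRow(gene=f"SYNG:g{i + 1}", fold_change=fc, fdr=fdr)
        )
    return rows, manifest


def write_expression_table(rows: list[ExpressionRow], path) -> None:
    """Write rows in the expression TSV dialect (``gene, fold_change, fdr``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tfold_change\tfdr\n")
        for r in rows:
            fh.write(f"{r.gene}\t{r.fold_change!r}\t{r.fdr!r}\n")


# ---------------------------------------------------------------------------
# randomized specs/templates for property testing


def random_spec(
    seed: int,
    max_nodes: int = 40,
    n_groups: int = 4,
    n_relations: int = 3,
) -> SyntheticSpec:
    """Random small-graph recipe: a few groups, a few relation types."""
    rng = random.Random(seed)
    groups = rng.sample(sorted(SemanticGroup, key=lambda g: g.value),
                        n_groups)
    counts = {}
    budget = rng.randint(n_groups, max_nodes)
    for g in groups:
        counts[g] = rng.randint(1, max(1, budget // n_groups))
    labels = [f"relation {chr(97 + i)}" for i in range(n_relations)]
    relations = []
    for label in labels:
        sg = rng.choice(groups)
        og = rng.choice(groups)
        max_pairs = counts[sg] * counts[og] - (
            counts[sg] if sg is og else 0
        )
        if max_pairs <= 0:
            continue
        relations.append(
            RelationSpec(
                label=label,
                subject_group=sg,
                object_group=og,
                count=rng.randint(1, max_pairs),
            )
        )
    return SyntheticSpec(
        node_counts=counts, relations=tuple(relations), seed=seed
    )


def random_template(
    seed: int,
    spec: SyntheticSpec,
    graph: KnowledgeGraph,
    max_length: int = 4,
) -> MetapathTemplate:
    """Random template over a graph's groups/labels, sometimes anchored."""
    rng = random.Random(seed)
    length = rng.randint(1, max_length)
    groups = sorted(spec.node_counts, key=lambda g: g.value)
    labels = [r.label for r in spec.relations]
    node_constraints = []
    for pos in range(length + 1):
        roll = rng.random()
        if roll < 0.2 and graph.n_nodes:
            anchor = rng.choice(sorted(graph.nodes))
            node_constraints.append(
                NodeConstraint(fixed_id=graph.nodes[anchor].id)
            )
        elif roll < 0.6:
            chosen = rng.sample(groups, rng.randint(1, len(groups)))
            node_constraints.append(
                NodeConstraint(groups=frozenset(chosen))
            )
        else:
            node_constraints.append(NodeConstraint())
    edge_constraints = []
    for _ in range(length):
        direction = rng.choice((FORWARD, REVERSE, ANY, ANY))
        if labels and rng.random() < 0.5:
            chosen = rng.sample(labels, rng.randint(1, len(labels)))
            edge_constraints.append(
                EdgeConstraint(
                    property_labels=frozenset(chosen),
                    direction=direction,
                )
            )
        else:
            edge_constraints.append(EdgeConstraint(direction=direction))
    return MetapathTemplate(
        node_constraints=tuple(node_constraints),
        edge_constraints=tuple(edge_constraints),
    )
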