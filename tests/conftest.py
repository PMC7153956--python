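import pytest

from kgreview.datamodel import (
    Curie,
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
    SemanticGroup,
    parse_curie,
)


def make_edge(s: str, p: str, o: str, label: str = "", **kw) -> EdgeRecord:
    return EdgeRecord(
        subject=parse_curie(s),
        property_id=parse_curie(p),
        object=parse_curie(o),
        property_label=label,
        **kw,
    )


def make_node(
    nid: str, group: SemanticGroup = SemanticGroup.GENE, **kw
) -> NodeRecord:
    return NodeRecord(id=parse_curie(nid), semantic_group=group, **kw)


@pytest.fixture
def star_graph() -> KnowledgeGraph:
    """One GENE hub with five DISO leaves (hub -> leaf edges)."""
    g = KnowledgeGraph()
    g.add_node(make_node("HGNC:1"))
    for i in range(5):
        g.add_node(make_node(f"HP:{i}", SemanticGroup.DISO))
        g.add_edge(
            make_edge("HGNC:1", "RO:0002200", f"HP:{i}", "has phenotype")
        )
    return g


@pytest.fixture
def chain_graph() -> KnowledgeGraph:
    """a - b - c chain of interaction edges."""
    g = KnowledgeGraph()
    for nid in ("HGNC:a", "HGNC:b", "HGNC:c"):
        g.add_node(make_node(nid))
    g.add_edge(make_edge("HGNC:a", "RO:0002434", "HGNC:b", "interacts with"))
    g.add_edge(make_edge("HGNC:b", "RO:0002434", "HGNC:c", "interacts with"))
    return g
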