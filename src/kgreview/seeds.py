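"""Bundled seed list and query-topology fixtures.

The default review is seeded with the nine concepts at the centre of the
NGLY1 Deficiency case study: seven genes (NGLY1, AQP1 human and mouse,
ENGASE, NFE2L1, AQP3, AQP11), the metabolite GlcNAc and the disease NGLY1
Deficiency.  The two shipped query topologies (regulatory hypothesis,
phenotype hypothesis) are editable JSON fixtures, not hard-coded truth.
"""

from __future__ import annotations

import os

from .datamodel import KnowledgeGraph, NodeRecord
from .ingest import read_node_table

_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")

SEED_TABLE = os.path.join(_DATA_DIR, "seeds_ngly1.tsv")
REGULATORY_TEMPLATE = os.path.join(
    _DATA_DIR, "templates", "regulatory_hypothesis.json"
)
PHENOTYPE_TEMPLATE = os.path.join(
    _DATA_DIR, "templates", "phenotype_hypothesis.json"
)


def seed_nodes() -> list[NodeRecord]:
    """The nine seed concepts, read through the Node TSV dialect."""
    return read_node_table(SEED_TABLE)


def seed_graph() -> KnowledgeGraph:
    """A graph containing exactly the seed nodes (no edges yet)."""
    g = KnowledgeGraph()
    for node in seed_nodes():
        g.add_node(node)
    return g
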