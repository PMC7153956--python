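"""Serialization of knowledge graphs: Neo4j bulk-import CSV, TSV, RDF.

Three dialects are supported:

* **Neo4j bulk-import CSV** — ``nodes.csv`` / ``edges.csv`` with the
  ``id:ID``, ``:LABEL``, ``:START_ID``, ``:TYPE``, ``:END_ID`` header
  convention, ready for ``neo4j-admin import``.  Relationship types are
  the upper-snake-cased property labels (the dialect forbids spaces).
* **Edge/Node TSV** — the package's own tabular dialect, lossless
  including provenance and reference dates.
* **RDF N-Triples** — one triple per statement plus one ``rdfs:label``
  triple per node, with CURIEs expanded through a prefix map.  Provenance
  is deliberately not reified; the RDF export targets interoperability,
  not provenance exchange.

All writers sort rows/lines so equal graphs produce byte-identical files.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Mapping

from rdflib import Graph as RdfGraph
from rdflib import Literal, URIRef
from rdflib.namespace import RDFS

from .datamodel import (
    Curie,
    EdgeRecord,
    KnowledgeGraph,
    NodeRecord,
    SemanticGroup,
    statement_key,
)
from .errors import DialectError, PrefixError
from .ingest import LIST_SEP, read_edge_table, read_node_table

__all__ = [
    "PrefixMap",
    "write_neo4j_csv",
    "read_neo4j_csv",
    "write_tsv",
    "read_tsv",
    "write_ntriples",
    "relation_type",
]

NODES_CSV_HEADER = [
    "id:ID",
    ":LABEL",
    "preflabel",
    "name",
    "synonyms",
    "description",
    "taxon",
]
EDGES_CSV_HEADER = [
    ":START_ID",
    ":TYPE",
    ":END_ID",
    "property_id",
    "property_uri",
    "reference_uri",
    "reference_supporting_text",
]


@dataclass
class PrefixMap:
    """CURIE prefix -> URI base (bases end with ``/`` or ``#``)."""

    bases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prefix, base in self.bases.items():
            if not base.endswith(("/", "#")):
                raise DialectError(
                    f"URI base for prefix {prefix!r} must end "
                    f"with '/' or '#': {base!r}"
                )

    def expand(self, curie: Curie) -> str:
        base = self.bases.get(curie.prefix)
        if base is None:
            raise PrefixError(
                f"no URI base for prefix {curie.prefix!r}"
            )
        return base + curie.local_id


def relation_type(label: str) -> str:
    """Neo4j relationship type: upper-cased label, spaces to underscores."""
    return label.strip().upper().replace(" ", "_")


def _label_from_type(rtype: str) -> str:
    return rtype.lower().replace("_", " ")


# ---------------------------------------------------------------------------
# Neo4j bulk-import CSV


def write_neo4j_csv(graph: KnowledgeGraph, directory: str | os.PathLike) -> None:
    """Write ``nodes.csv`` and ``edges.csv`` in bulk-import dialect.

    Array fields are pipe-delimited inside a single CSV field; RFC 4180
    quoting applies; rows are sorted by id / statement key so output is
    byte-stable.
    """
    os.makedirs(directory, exist_ok=True)
    with open(
        os.path.join(directory, "nodes.csv"), "w", encoding="utf-8",
        newline="",
    ) as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(NODES_CSV_HEADER)
        for key in sorted(graph.nodes):
            n = graph.nodes[key]
            writer.writerow(
                [
                    str(n.id),
                    n.semantic_group.value,
                    n.preflabel,
                    n.name,
                    LIST_SEP.join(n.synonyms),
                    n.description,
                    n.taxon,
                ]
            )
    with open(
        os.path.join(directory, "edges.csv"), "w", encoding="utf-8",
        newline="",
    ) as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(EDGES_CSV_HEADER)
        for e in sorted(graph.edges, key=statement_key):
            writer.writerow(
                [
                    str(e.subject),
                    relation_type(e.property_label or e.property_id.local_id),
                    str(e.object),
                    str(e.property_id),
                    e.property_uri,
                    LIST_SEP.join(e.reference_uri),
                    e.reference_supporting_text,
                ]
            )


def read_neo4j_csv(directory: str | os.PathLike) -> KnowledgeGraph:
    """Inverse of :func:`write_neo4j_csv` on its own output."""
    from .datamodel import parse_curie

    nodes_path = os.path.join(directory, "nodes.csv")
    edges_path = os.path.join(directory, "edges.csv")
    for path, header in (
        (nodes_path, NODES_CSV_HEADER),
        (edges_path, EDGES_CSV_HEADER),
    ):
        if not os.path.exists(path):
            raise DialectError(f"missing bulk-import file: {path}")
        with open(path, encoding="utf-8", newline="") as fh:
            first = next(csv.reader(fh), None)
        if first != header:
            raise DialectError(
                f"{path}: header mismatch, expected {header}, got {first}"
            )

    graph = KnowledgeGraph()
    with open(nodes_path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            nid, label, preflabel, name, synonyms, description, taxon = row
            graph.add_node(
                NodeRecord(
                    id=parse_curie(nid),
                    semantic_group=SemanticGroup(label),
                    preflabel=preflabel,
                    name=name,
                    synonyms=[s for s in synonyms.split(LIST_SEP) if s],
                    description=description,
                    taxon=taxon,
                )
            )
    with open(edges_path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            start, rtype, end, pid, puri, refs, text = row
            graph.add_edge(
                EdgeRecord(
                    subject=parse_curie(start),
                    property_id=parse_curie(pid),
                    object=parse_curie(end),
                    property_label=_label_from_type(rtype),
                    property_uri=puri,
                    reference_uri=[r for r in refs.split(LIST_SEP) if r],
                    reference_supporting_text=text,
                )
            )
    return graph


# ---------------------------------------------------------------------------
# TSV (lossless round-trip dialect)


def write_tsv(graph: KnowledgeGraph, directory: str | os.PathLike) -> None:
    """Write ``nodes.tsv`` / ``edges.tsv`` in the package dialect.

    This form is lossless: it carries every node and edge attribute,
    including reference dates, and round-trips through the ingest
    readers.  Tab characters inside fields are forbidden by the dialect.
    """
    os.makedirs(directory, exist_ok=True)

    def _check(value: str, where: str) -> str:
        if "\t" in value or "\n" in value:
            raise DialectError(
                f"TSV dialect forbids tabs/newlines in fields ({where})"
            )
        return value

    with open(
        os.path.join(directory, "nodes.tsv"), "w", encoding="utf-8"
    ) as fh:
        fh.write(
            "id\tsemantic_group\tpreflabel\tname\tsynonyms"
            "\tdescription\ttaxon\n"
        )
        for key in sorted(graph.nodes):
            n = graph.nodes[key]
            fields = [
                str(n.id),
                n.semantic_group.value,
                n.preflabel,
                n.name,
                LIST_SEP.join(n.synonyms),
                n.description,
                n.taxon,
            ]
            fh.write(
                "\t".join(_check(f, f"node {key}") for f in fields) + "\n"
            )
    with open(
        os.path.join(directory, "edges.tsv"), "w", encoding="utf-8"
    ) as fh:
        fh.write(
            "subject_id\tproperty_id\tobject_id\tproperty_label"
            "\tproperty_uri\treference_uri\treference_supporting_text"
            "\treference_date\n"
        )
        for e in sorted(graph.edges, key=statement_key):
            fields = [
                str(e.subject),
                str(e.property_id),
                str(e.object),
                e.property_label,
                e.property_uri,
                LIST_SEP.join(e.reference_uri),
                e.reference_supporting_text,
                e.reference_date,
            ]
            fh.write(
                "\t".join(
                    _check(f, f"edge {statement_key(e)}") for f in fields
                )
                + "\n"
            )


def read_tsv(directory: str | os.PathLike) -> KnowledgeGraph:
    """Read a graph written by :func:`write_tsv`."""
    nodes = read_node_table(os.path.join(directory, "nodes.tsv"))
    edges = read_edge_table(os.path.join(directory, "edges.tsv"))
    graph = KnowledgeGraph()
    for n in nodes:
        graph.add_node(n)
    graph.add_edges(edges)
    return graph


# ---------------------------------------------------------------------------
# RDF N-Triples


def write_ntriples(
    graph: KnowledgeGraph,
    path: str | os.PathLike,
    prefixes: PrefixMap | Mapping[str, str],
) -> None:
    """Write the graph as RDF N-Triples.

    One triple per statement (subject, relation URI, object) and one
    ``rdfs:label`` triple per node carrying the preferred label.  Every
    prefix occurring in the graph must be mapped; otherwise a
    :class:`PrefixError` names the offender.  Lines are sorted for
    deterministic output.
    """
    if not isinstance(prefixes, PrefixMap):
        prefixes = PrefixMap(dict(prefixes))
    rdf = RdfGraph()
    for node in graph.nodes.values():
        uri = URIRef(prefixes.expand(node.id))
        if node.preflabel:
            rdf.add((uri, RDFS.label, Literal(node.preflabel)))
    for edge in graph.iter_edges():
        if edge.property_uri:
            predicate = URIRef(edge.property_uri)
        else:
            predicate = URIRef(prefixes.expand(edge.property_id))
        rdf.add(
            (
                URIRef(prefixes.expand(edge.subject)),
                predicate,
                URIRef(prefixes.expand(edge.object)),
            )
        )
    serialized = rdf.serialize(format="nt")
    lines = sorted(line for line in serialized.splitlines() if line.strip())
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
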