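"""Readers for the file-based source dialects feeding a structured review.

Every remote service used when assembling a review by hand (knowledge-base
APIs, SPARQL endpoints, annotation services) is replaced here by a
pre-fetched table, which makes review construction reproducible and
versionable.  Dialects:

* Node TSV: ``id, semantic_group, preflabel, name, synonyms, description,
  taxon`` — synonyms pipe-separated.
* Edge TSV: ``subject_id, property_id, object_id, property_label,
  property_uri, reference_uri, reference_supporting_text, reference_date``
  — reference_uri pipe-separated.
* GMT: the Broad gene-set format, one regulon per line
  (``name TAB description TAB member...``).
* Expression TSV: ``gene, fold_change, fdr`` (columns remappable).
* Xref TSV: two columns ``source_id, target_id``.
* Ortholog pair TSV: ``gene_a, taxon_a, gene_b, taxon_b``; ortholog
  phenotype TSV: ``gene, phenotype, reference``.

All files are UTF-8 with a header row; fields may not contain tabs.
Readers never silently drop data rows: a row is either converted or
rejected with a line-numbered error (self-referential xref rows, which are
meaningless, are dropped with a logged warning).
"""

from __future__ import annotations

import csv
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .datamodel import (
    Curie,
    EdgeRecord,
    NodeRecord,
    SemanticGroup,
    as_curie,
    parse_curie,
)
from .errors import (
    DialectError,
    InputError,
    MalformedIdentifierError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegulonSet",
    "ExpressionRow",
    "XrefMap",
    "OrthologTable",
    "read_edge_table",
    "read_node_table",
    "read_gmt_regulons",
    "read_expression_table",
    "read_xref_table",
    "read_ortholog_table",
    "read_relation_map",
]

LIST_SEP = "|"

EDGE_COLUMNS = (
    "subject_id",
    "property_id",
    "object_id",
    "property_label",
    "property_uri",
    "reference_uri",
    "reference_supporting_text",
    "reference_date",
)
EDGE_REQUIRED = ("subject_id", "property_id", "object_id")

NODE_COLUMNS = (
    "id",
    "semantic_group",
    "preflabel",
    "name",
    "synonyms",
    "description",
    "taxon",
)
NODE_REQUIRED = ("id",)


@dataclass
class RegulonSet:
    """A transcription factor and its annotated target genes."""

    regulator: str
    targets: list[str]
    source_tag: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(
                f"regulon {self.regulator!r} has no targets"
            )


@dataclass
class ExpressionRow:
    """One gene of a differential-expression table.

    ``fold_change`` is a signed linear fold change (down-regulation
    negative); ``fdr`` the FDR-adjusted p-value.
    """

    gene: str
    fold_change: float
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(
                f"fdr {self.fdr} outside [0, 1] for gene {self.gene!r}"
            )
        if not math.isfinite(self.fold_change) or self.fold_change == 0:
            raise ValidationError(
                f"fold change {self.fold_change} invalid "
                f"for gene {self.gene!r}"
            )


@dataclass
class XrefMap:
    """Multimap from a source identifier to candidate target identifiers."""

    mapping: dict[str, list[Curie]] = field(default_factory=dict)

    def add(self, source: Curie, target: Curie) -> None:
        if str(source) == str(target):
            logger.warning("dropping self-referential xref %s", source)
            return
        bucket = self.mapping.setdefault(str(source), [])
        if all(str(t) != str(target) for t in bucket):
            bucket.append(target)

    def candidates(self, source: Curie | str) -> list[Curie]:
        return list(self.mapping.get(str(source), []))

    def __contains__(self, source: Curie | str) -> bool:
        return str(source) in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class OrthologTable:
    """Cross-species ortholog pairs plus ortholog-phenotype annotations."""

    pairs: list[tuple[Curie, str, Curie, str]] = field(default_factory=list)
    phenotypes: list[tuple[Curie, Curie, str]] = field(default_factory=list)

    def add_pair(
        self, gene_a: Curie, taxon_a: str, gene_b: Curie, taxon_b: str
    ) -> None:
        if taxon_a == taxon_b:
            raise ValidationError(
                f"ortholog pair {gene_a}/{gene_b} has identical "
                f"taxa {taxon_a!r}"
            )
        key = frozenset((str(gene_a), str(gene_b)))
        for a, _, b, _ in self.pairs:
            if frozenset((str(a), str(b))) == key:
                return
        self.pairs.append((gene_a, taxon_a, gene_b, taxon_b))

    def partners_of(self, gene: Curie | str) -> list[tuple[Curie, str]]:
        gid = str(gene)
        out = []
        for a, ta, b, tb in self.pairs:
            if str(a) == gid:
                out.append((b, tb))
            elif str(b) == gid:
                out.append((a, ta))
        return out

    def phenotypes_of(self, gene: Curie | str) -> list[tuple[Curie, str]]:
        gid = str(gene)
        return [(p, ref) for g, p, ref in self.phenotypes if str(g) == gid]


# ---------------------------------------------------------------------------
# low-level TSV plumbing


def _open_rows(path: str | os.PathLike) -> tuple[list[str], list[list[str]]]:
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if not rows:
        raise DialectError(f"{path}: empty file, header row required")
    return rows[0], rows[1:]


def _resolve_columns(
    header: Sequence[str],
    required: Sequence[str],
    optional: Sequence[str],
    column_map: Optional[Mapping[str, str]],
    path: str | os.PathLike,
) -> dict[str, int]:
    """Map canonical column names to indices, honouring a remap config.

    *column_map* maps canonical name -> actual header name, letting
    differently-labelled exports feed the same reader.
    """
    column_map = dict(column_map or {})
    index: dict[str, int] = {}
    positions = {name: i for i, name in enumerate(header)}
    for canonical in tuple(required) + tuple(optional):
        actual = column_map.get(canonical, canonical)
        if actual in positions:
            index[canonical] = positions[actual]
        elif canonical in required:
            raise DialectError(
                f"{path}: missing required column {actual!r}"
            )
    return index


def _cell(row: Sequence[str], index: dict[str, int], name: str) -> str:
    i = index.get(name)
    if i is None or i >= len(row):
        return ""
    return row[i].strip()


def _row_curie(
    text: str, path: str | os.PathLike, lineno: int, column: str
) -> Curie:
    try:
        return parse_curie(text)
    except MalformedIdentifierError as exc:
        raise DialectError(
            f"{path}:{lineno}: column {column!r}: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# readers


def read_edge_table(
    path: str | os.PathLike,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[EdgeRecord]:
    """Read an Edge TSV into :class:`EdgeRecord` objects.

    ``reference_uri`` cells are split on ``|``; blank optional fields map
    to empty values.  Missing required columns raise a
    :class:`DialectError`; malformed CURIEs raise with the line number.
    """
    header, rows = _open_rows(path)
    optional = tuple(c for c in EDGE_COLUMNS if c not in EDGE_REQUIRED)
    index = _resolve_columns(header, EDGE_REQUIRED, optional, column_map, path)
    edges: list[EdgeRecord] = []
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        edges.append(
            EdgeRecord(
                subject=_row_curie(
                    _cell(row, index, "subject_id"), path, lineno,
                    "subject_id",
                ),
                property_id=_row_curie(
                    _cell(row, index, "property_id"), path, lineno,
                    "property_id",
                ),
                object=_row_curie(
                    _cell(row, index, "object_id"), path, lineno,
                    "object_id",
                ),
                property_label=_cell(row, index, "property_label"),
                property_uri=_cell(row, index, "property_uri"),
                reference_uri=[
                    u
                    for u in _cell(row, index, "reference_uri").split(
                        LIST_SEP
                    )
                    if u
                ],
                reference_supporting_text=_cell(
                    row, index, "reference_supporting_text"
                ),
                reference_date=_cell(row, index, "reference_date"),
            )
        )
    return edges


def read_node_table(
    path: str | os.PathLike,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[NodeRecord]:
    """Read a Node TSV into :class:`NodeRecord` objects."""
    header, rows = _open_rows(path)
    optional = tuple(c for c in NODE_COLUMNS if c not in NODE_REQUIRED)
    index = _resolve_columns(header, NODE_REQUIRED, optional, column_map, path)
    nodes: list[NodeRecord] = []
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        group_text = _cell(row, index, "semantic_group") or "UNKNOWN"
        try:
            group = SemanticGroup(group_text)
        except ValueError as exc:
            raise DialectError(
                f"{path}:{lineno}: unknown semantic group {group_text!r}"
            ) from exc
        nodes.append(
            NodeRecord(
                id=_row_curie(_cell(row, index, "id"), path, lineno, "id"),
                semantic_group=group,
                preflabel=_cell(row, index, "preflabel"),
                name=_cell(row, index, "name"),
                synonyms=[
                    s
                    for s in _cell(row, index, "synonyms").split(LIST_SEP)
                    if s
                ],
                description=_cell(row, index, "description"),
                taxon=_cell(row, index, "taxon"),
            )
        )
    return nodes


def read_gmt_regulons(
    path: str | os.PathLike, source_tag: str = ""
) -> list[RegulonSet]:
    """Read TF regulons from a GMT gene-set file.

    Per line: set name, description, then one member gene per field.  The
    regulator is the set name; duplicate members are removed preserving
    first-seen order.
    """
    if not os.path.exists(path):
        raise InputError(f"input file not found: {path}")
    regulons: list[RegulonSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DialectError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, "
                    f"got {len(fields)}"
                )
            seen: dict[str, None] = {}
            for member in fields[2:]:
                member = member.strip()
                if member:
                    seen.setdefault(member, None)
            if not seen:
                raise DialectError(
                    f"{path}:{lineno}: gene set {fields[0]!r} has no members"
                )
            regulons.append(
                RegulonSet(
                    regulator=fields[0].strip(),
                    targets=list(seen),
                    source_tag=source_tag,
                    description=fields[1].strip(),
                )
            )
    return regulons


def read_expression_table(
    path: str | os.PathLike,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[ExpressionRow]:
    """Read a differential-expression TSV (``gene, fold_change, fdr``)."""
    header, rows = _open_rows(path)
    index = _resolve_columns(
        header, ("gene", "fold_change", "fdr"), (), column_map, path
    )
    out: list[ExpressionRow] = []
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        gene = _cell(row, index, "gene")
        try:
            fc = float(_cell(row, index, "fold_change"))
            fdr = float(_cell(row, index, "fdr"))
        except ValueError as exc:
            raise DialectError(
                f"{path}:{lineno}: non-numeric fold_change/fdr"
            ) from exc
        try:
            out.append(ExpressionRow(gene=gene, fold_change=fc, fdr=fdr))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_xref_table(path: str | os.PathLike) -> XrefMap:
    """Read a two-column cross-reference TSV into an :class:`XrefMap`."""
    header, rows = _open_rows(path)
    index = _resolve_columns(
        header, ("source_id", "target_id"), (), None, path
    )
    xref = XrefMap()
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        src = _row_curie(
            _cell(row, index, "source_id"), path, lineno, "source_id"
        )
        tgt = _row_curie(
            _cell(row, index, "target_id"), path, lineno, "target_id"
        )
        xref.add(src, tgt)
    return xref


def read_ortholog_table(
    path_pairs: str | os.PathLike,
    path_phenotypes: Optional[str | os.PathLike] = None,
) -> OrthologTable:
    """Read ortholog pairs and, optionally, ortholog-phenotype annotations.

    Pair TSV columns: ``gene_a, taxon_a, gene_b, taxon_b``; the two taxa
    must differ.  Phenotype TSV columns: ``gene, phenotype, reference``.
    """
    table = OrthologTable()
    header, rows = _open_rows(path_pairs)
    index = _resolve_columns(
        header, ("gene_a", "taxon_a", "gene_b", "taxon_b"), (), None,
        path_pairs,
    )
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        try:
            table.add_pair(
                _row_curie(
                    _cell(row, index, "gene_a"), path_pairs, lineno, "gene_a"
                ),
                _cell(row, index, "taxon_a"),
                _row_curie(
                    _cell(row, index, "gene_b"), path_pairs, lineno, "gene_b"
                ),
                _cell(row, index, "taxon_b"),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path_pairs}:{lineno}: {exc}") from exc
    if path_phenotypes is not None:
        header, rows = _open_rows(path_phenotypes)
        index = _resolve_columns(
            header, ("gene", "phenotype"), ("reference",), None,
            path_phenotypes,
        )
        for lineno, row in enumerate(rows, start=2):
            if not any(cell.strip() for cell in row):
                continue
            table.phenotypes.append(
                (
                    _row_curie(
                        _cell(row, index, "gene"), path_phenotypes, lineno,
                        "gene",
                    ),
                    _row_curie(
                        _cell(row, index, "phenotype"), path_phenotypes,
                        lineno, "phenotype",
                    ),
                    _cell(row, index, "reference"),
                )
            )
    return table


def read_relation_map(
    path: str | os.PathLike,
) -> dict[str, tuple[Curie, str]]:
    """Read a relation-semantics map TSV.

    Columns ``property_label, property_id, property_uri``; returns
    label -> (property id, property URI).
    """
    header, rows = _open_rows(path)
    index = _resolve_columns(
        header, ("property_label", "property_id"), ("property_uri",), None,
        path,
    )
    mapping: dict[str, tuple[Curie, str]] = {}
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        label = _cell(row, index, "property_label")
        pid = _row_curie(
            _cell(row, index, "property_id"), path, lineno, "property_id"
        )
        mapping[label] = (pid, _cell(row, index, "property_uri"))
    return mapping
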