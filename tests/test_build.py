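import random

import pytest
import yaml

from kgreview.build import (
    ReviewConfig,
    assemble_review,
    build_expression_edges,
    build_regulon_edges,
    expand_orthologs,
    merge_networks,
    neighborhood_expansion,
    network_from,
)
from kgreview.datamodel import KnowledgeGraph, SemanticGroup, parse_curie
from kgreview.errors import ConfigurationError, InputError
from kgreview.ingest import ExpressionRow, OrthologTable, RegulonSet
from kgreview.synthetic import random_spec, generate_graph

from conftest import make_edge, make_node


class TestMergeNetworks:
    def test_disjoint_networks_additive(self):
        a = network_from(
            [make_edge(f"A:{i}", "RO:1", f"A:{i + 10}") for i in range(3)]
        )
        b = network_from(
            [make_edge(f"B:{i}", "RO:1", f"B:{i + 10}") for i in range(4)]
        )
        merged = merge_networks([a, b])
        assert merged.n_edges == 7
        assert merged.n_nodes == a.n_nodes + b.n_nodes

    def test_shared_statement_collapses_with_reference_union(self):
        a = network_from(
            [make_edge("A:1", "RO:1", "A:2", reference_uri=["u1"])]
        )
        b = network_from(
            [make_edge("A:1", "RO:1", "A:2", reference_uri=["u2"])]
        )
        merged = merge_networks([a, b])
        assert merged.n_edges == 1
        assert merged.edges[0].reference_uri == ["u1", "u2"]

    def test_merge_with_empty_is_identity(self, star_graph):
        assert merge_networks([star_graph, KnowledgeGraph()]) == star_graph

    def test_commutative_and_idempotent_on_random_pairs(self):
        for seed in range(10):
            g1, _ = generate_graph(random_spec(seed, max_nodes=20))
            g2, _ = generate_graph(random_spec(seed + 1000, max_nodes=20))
            ab = merge_networks([g1, g2])
            ba = merge_networks([g2, g1])
            assert ab == ba
            assert merge_networks([ab, g1]) == ab

    def test_associative(self):
        gs = [
            generate_graph(random_spec(s, max_nodes=15))[0]
            for s in (1, 2, 3)
        ]
        left = merge_networks([merge_networks(gs[:2]), gs[2]])
        right = merge_networks([gs[0], merge_networks(gs[1:])])
        assert left == right


class TestNeighborhoodExpansion:
    def test_star_one_hop(self, star_graph):
        out = neighborhood_expansion(
            star_graph, [parse_curie("HGNC:1")], hops=1
        )
        assert out.n_nodes == 6 and out.n_edges == 5

    def test_chain_one_hop_from_end(self, chain_graph):
        out = neighborhood_expansion(
            chain_graph, [parse_curie("HGNC:a")], hops=1
        )
        assert set(out.nodes) == {"HGNC:a", "HGNC:b"}
        assert out.n_edges == 1

    def test_expansion_ignores_direction(self, star_graph):
        # leaves only have incoming edges; they still reach the hub
        out = neighborhood_expansion(
            star_graph, [parse_curie("HP:0")], hops=1
        )
        assert "HGNC:1" in out

    def test_zero_hops_returns_seeds_only(self, chain_graph):
        out = neighborhood_expansion(
            chain_graph, [parse_curie("HGNC:a")], hops=0
        )
        assert set(out.nodes) == {"HGNC:a"} and out.n_edges == 0

    def test_absent_seed_warns_not_fatal(self, chain_graph, caplog):
        out = neighborhood_expansion(
            chain_graph, [parse_curie("HGNC:zz")], hops=1
        )
        assert out.n_nodes == 0

    def test_empty_seed_list_rejected(self, chain_graph):
        with pytest.raises(ConfigurationError):
            neighborhood_expansion(chain_graph, [], hops=1)

    def test_monotone_in_hops(self):
        g, _ = generate_graph(random_spec(11, max_nodes=30))
        seeds = [g.nodes[sorted(g.nodes)[0]].id]
        previous: set[str] = set()
        for hops in range(4):
            nodes = set(neighborhood_expansion(g, seeds, hops).nodes)
            assert previous <= nodes
            previous = nodes


class TestExpandOrthologs:
    def _table(self) -> OrthologTable:
        t = OrthologTable()
        t.add_pair(parse_curie("HGNC:1"), "human",
                   parse_curie("FlyBase:1"), "fly")
        t.add_pair(parse_curie("HGNC:99"), "human",
                   parse_curie("FlyBase:99"), "fly")
        t.phenotypes.append(
            (parse_curie("FlyBase:1"), parse_curie("HP:1"), "http://r/1")
        )
        t.phenotypes.append(
            (parse_curie("FlyBase:99"), parse_curie("HP:9"), "")
        )
        return t

    def test_only_in_graph_genes_expand(self):
        g = KnowledgeGraph()
        g.add_node(make_node("HGNC:1"))
        out = expand_orthologs(g, self._table())
        assert "FlyBase:1" in out and "HP:1" in out
        assert "HGNC:99" not in out and "FlyBase:99" not in out
        assert out.n_edges == 2  # orthology + phenotype

    def test_empty_table_no_change(self, star_graph):
        assert expand_orthologs(star_graph, OrthologTable()) == star_graph

    def test_idempotent(self):
        g = KnowledgeGraph()
        g.add_node(make_node("HGNC:1"))
        once = expand_orthologs(g, self._table())
        assert expand_orthologs(once, self._table()) == once

    def test_phenotypes_only_for_new_orthologs(self):
        # gene already in graph: orthology edge added, but it is not a
        # NEW ortholog, so its phenotype annotations are not pulled in
        g = KnowledgeGraph()
        g.add_node(make_node("HGNC:1"))
        g.add_node(make_node("FlyBase:1"))
        out = expand_orthologs(g, self._table())
        assert "HP:1" not in out


class TestExpressionEdges:
    SOURCE = parse_curie("FlyBase:FBgn0033050")

    def rows(self):
        return [
            ExpressionRow("g1", 2.0, 0.01),
            ExpressionRow("g2", 1.2, 0.001),
            ExpressionRow("g3", -1.8, 0.04),
            ExpressionRow("g4", 1.9, 0.2),
        ]

    def test_strict_filter_selects_expected_rows(self):
        edges = build_expression_edges(self.rows(), self.SOURCE)
        assert [e.object.local_id for e in edges] == ["g1", "g3"]
        assert all(e.property_label == "interacts with" for e in edges)

    def test_boundary_rows_excluded(self):
        rows = [
            ExpressionRow("g5", 1.5, 0.01),
            ExpressionRow("g6", -1.5, 0.01),
            ExpressionRow("g7", 2.0, 0.05),
        ]
        assert build_expression_edges(rows, self.SOURCE) == []

    def test_empty_table(self):
        assert build_expression_edges([], self.SOURCE) == []

    def test_supporting_text_records_evidence(self):
        edges = build_expression_edges(
            [ExpressionRow("g1", -2.5, 0.004)], self.SOURCE
        )
        text = edges[0].reference_supporting_text
        assert "-2.5" in text and "0.004" in text

    def test_log2_switch(self):
        rows = [ExpressionRow("g1", 1.0, 0.01)]  # log2 FC 1.0 = linear 2.0
        assert build_expression_edges(rows, self.SOURCE) == []
        assert len(
            build_expression_edges(rows, self.SOURCE, log2_fold_change=True)
        ) == 1

    def test_count_matches_row_by_row_check(self):
        rng = random.Random(7)
        rows = [
            ExpressionRow(
                f"g{i}",
                rng.uniform(-4, 4) or 0.1,
                rng.random(),
            )
            for i in range(200)
        ]
        expected = sum(
            1 for r in rows if abs(r.fold_change) > 1.5 and r.fdr < 0.05
        )
        assert len(build_expression_edges(rows, self.SOURCE)) == expected


class TestRegulonEdges:
    def test_tf_target_edges(self):
        regs = [RegulonSet("TF1", ["G1", "G2"], source_tag="ENCODE")]
        edges = build_regulon_edges(regs)
        assert len(edges) == 2
        assert all(e.property_label == "regulates" for e in edges)
        assert str(edges[0].subject) == "SYMBOL:TF1"


class TestAssembleReview:
    EDGE_HEADER = (
        "subject_id\tproperty_id\tobject_id\tproperty_label\tproperty_uri"
        "\treference_uri\treference_supporting_text\treference_date\n"
    )

    def _write_sources(self, tmp_path):
        (tmp_path / "net1.tsv").write_text(
            self.EDGE_HEADER
            + "HGNC:17646\tRO:1\tHGNC:633\tinteracts with\t\tu1\t\t\n",
            encoding="utf-8",
        )
        (tmp_path / "net2.tsv").write_text(
            self.EDGE_HEADER
            + "HGNC:633\tRO:2\tHP:5\thas phenotype\t\tu2\t\t\n",
            encoding="utf-8",
        )

    def _config(self, tmp_path, **extra):
        raw = {
            "seeds": ["HGNC:17646"],
            "hops": 2,
            "sources": [
                {"path": "net1.tsv", "kind": "edges"},
                {"path": "net2.tsv", "kind": "edges"},
            ],
        }
        raw.update(extra)
        path = tmp_path / "review.yaml"
        path.write_text(yaml.safe_dump(raw), encoding="utf-8")
        return path

    def test_composition_equals_individual_merge(self, tmp_path):
        self._write_sources(tmp_path)
        config = ReviewConfig.from_file(self._config(tmp_path))
        graph, manifest = assemble_review(config)
        assert graph.n_edges == 2
        assert {"HGNC:17646", "HGNC:633", "HP:5"} <= set(graph.nodes)
        assert manifest["graph_summary"]["n_edges"] == 2

    def test_missing_file_is_fatal_naming_path(self, tmp_path):
        self._write_sources(tmp_path)
        config_path = self._config(
            tmp_path,
            sources=[{"path": "absent.tsv", "kind": "edges"}],
        )
        with pytest.raises(InputError, match="absent.tsv"):
            assemble_review(ReviewConfig.from_file(config_path))

    def test_deterministic_rerun(self, tmp_path):
        self._write_sources(tmp_path)
        config_path = self._config(tmp_path)
        g1, _ = assemble_review(ReviewConfig.from_file(config_path))
        g2, _ = assemble_review(ReviewConfig.from_file(config_path))
        assert g1 == g2

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            ReviewConfig(seeds=[])
        with pytest.raises(ConfigurationError):
            ReviewConfig(
                seeds=[parse_curie("HGNC:1")], fdr_max=1.7
            )
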