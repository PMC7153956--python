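import json

import pytest

from kgreview.datamodel import KnowledgeGraph, SemanticGroup, parse_curie
from kgreview.errors import ValidationError
from kgreview.metapath import (
    EdgeConstraint,
    MetapathTemplate,
    NodeConstraint,
    compile_template,
    enumerate_paths,
    summarize_paths,
)
from kgreview.normalize import EXACT_MATCH_ID
from kgreview.synthetic import (
    generate_graph,
    plant_template_instances,
    random_spec,
    random_template,
)

from conftest import make_edge, make_node
from oracle import oracle_paths


def wildcard_template(length: int) -> MetapathTemplate:
    return MetapathTemplate(
        node_constraints=tuple(NodeConstraint() for _ in range(length + 1)),
        edge_constraints=tuple(EdgeConstraint() for _ in range(length)),
    )


class TestCompileTemplate:
    def test_length_four_document(self):
        doc = {
            "nodes": [{}, {"groups": ["GENE"]}, {}, {}, {"id": "HGNC:633"}],
            "edges": [{}, {"labels": ["regulates"]}, {}, {
                "direction": "forward"
            }],
        }
        t = compile_template(doc)
        assert t.length == 4
        assert t.node_constraints[-1].fixed_id == parse_curie("HGNC:633")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            compile_template({"nodes": [{}, {}, {}], "edges": [{}, {}, {}]})

    def test_minimal_wildcard_template(self):
        t = compile_template({"nodes": [{}, {}], "edges": [{}]})
        assert t.length == 1

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            compile_template(
                {"nodes": [{"groups": ["WIDGET"]}, {}], "edges": [{}]}
            )

    def test_empty_constraint_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            compile_template(
                {"nodes": [{"groups": []}, {}], "edges": [{}]}
            )
        with pytest.raises(ValidationError, match="empty"):
            compile_template(
                {"nodes": [{}, {}], "edges": [{"labels": []}]}
            )

    def test_json_string_accepted(self):
        t = compile_template(json.dumps({"nodes": [{}, {}], "edges": [{}]}))
        assert t.length == 1


class TestEnumerate:
    def test_single_planted_chain_found(self):
        g = KnowledgeGraph()
        t = compile_template(
            {
                "nodes": [
                    {"id": "HGNC:a"},
                    {"groups": ["GENE"]},
                    {"groups": ["GENE"]},
                    {"groups": ["GENE"]},
                    {"id": "HGNC:e"},
                ],
                "edges": [{}, {}, {}, {}],
            }
        )
        g2, truth = plant_template_instances(g, t, k=1, seed=3)
        paths = enumerate_paths(g2, t)
        assert list(paths) == truth.planted_paths

    def test_anchored_endpoints_no_connection(self, chain_graph):
        t = compile_template(
            {
                "nodes": [{"id": "HGNC:a"}, {"id": "HGNC:c"}],
                "edges": [{}],
            }
        )
        assert list(enumerate_paths(chain_graph, t)) == []

    def test_direction_semantics(self, chain_graph):
        # stored: a->b; reverse-only constraint must reject a->b travel
        forward = compile_template(
            {
                "nodes": [{"id": "HGNC:a"}, {"id": "HGNC:b"}],
                "edges": [{"direction": "forward"}],
            }
        )
        reverse = compile_template(
            {
                "nodes": [{"id": "HGNC:a"}, {"id": "HGNC:b"}],
                "edges": [{"direction": "reverse"}],
            }
        )
        assert len(enumerate_paths(chain_graph, forward)) == 1
        assert len(enumerate_paths(chain_graph, reverse)) == 0

    def test_simple_paths_no_repeated_node(self):
        g = KnowledgeGraph()
        g.add_edge(make_edge("A:1", "RO:1", "A:2", "r"))
        g.add_edge(make_edge("A:2", "RO:1", "A:1", "r"))
        paths = enumerate_paths(g, wildcard_template(2))
        assert paths == []  # any 2-step walk would revisit a node

    def test_exact_match_edges_invisible_to_wildcards(self):
        g = KnowledgeGraph()
        g.add_edge(
            make_edge("OMIM:1", "skos:exactMatch", "MONDO:1", "exact match")
        )
        assert enumerate_paths(g, wildcard_template(1)) == []
        named = MetapathTemplate(
            node_constraints=(NodeConstraint(), NodeConstraint()),
            edge_constraints=(
                EdgeConstraint(
                    property_ids=frozenset({str(EXACT_MATCH_ID)}),
                    direction="forward",
                ),
            ),
        )
        assert len(enumerate_paths(g, named)) == 1

    def test_limit_sets_truncation_flag(self, star_graph):
        t = wildcard_template(1)
        full = enumerate_paths(star_graph, t)
        capped = enumerate_paths(star_graph, t, limit=3)
        assert len(capped) == 3 and capped.truncated
        assert not full.truncated
        assert list(capped) == list(full)[:3]

    def test_deterministic_lexicographic_order(self, star_graph):
        paths = enumerate_paths(star_graph, wildcard_template(1))
        keys = [(p.nodes, p.edges) for p in paths]
        assert keys == sorted(keys)

    def test_anchoring_consistency(self):
        g, _ = generate_graph(random_spec(21, max_nodes=30))
        t = wildcard_template(2)
        all_paths = set(enumerate_paths(g, t))
        some = next(iter(all_paths), None)
        if some is None:
            pytest.skip("random graph produced no 2-paths")
        start = parse_curie(some.nodes[0])
        end = parse_curie(some.nodes[-1])

        def anchored(first, last):
            ncs = list(t.node_constraints)
            if first is not None:
                ncs[0] = NodeConstraint(fixed_id=first)
            if last is not None:
                ncs[-1] = NodeConstraint(fixed_id=last)
            return set(
                enumerate_paths(
                    g,
                    MetapathTemplate(tuple(ncs), t.edge_constraints),
                )
            )

        both = anchored(start, end)
        assert both <= anchored(start, None) <= all_paths
        assert both <= anchored(None, end) <= all_paths


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_engine_matches_brute_force(self, seed):
        spec = random_spec(seed, max_nodes=25)
        graph, _ = generate_graph(spec)
        template = random_template(seed * 7 + 1, spec, graph)
        engine = enumerate_paths(graph, template)
        assert len(engine) == len(set(engine))
        assert set(engine) == oracle_paths(graph, template)


class TestSummaries:
    def _paths_graph(self):
        g = KnowledgeGraph()
        t = compile_template(
            {
                "nodes": [{"id": "A:start"}, {"groups": ["GENE"]},
                          {"id": "A:end"}],
                "edges": [{}, {}],
            }
        )
        g, truth = plant_template_instances(g, t, k=3, seed=5)
        return g, t, enumerate_paths(g, t)

    def test_counts_sum_to_path_count(self):
        g, t, paths = self._paths_graph()
        summary = summarize_paths(paths, g, template=t)
        by_pos: dict[int, int] = {}
        for pos, _, _, count in summary.rows:
            by_pos[pos] = by_pos.get(pos, 0) + count
        assert all(total == len(paths) for total in by_pos.values())

    def test_anchored_positions_excluded(self):
        g, t, paths = self._paths_graph()
        summary = summarize_paths(paths, g, template=t)
        assert {pos for pos, *_ in summary.rows} == {1}

    def test_repeated_node_counted(self):
        g = KnowledgeGraph()
        for leaf in ("B:x", "B:y"):
            g.add_edge(make_edge("A:hub", "RO:1", leaf, "r"))
            g.add_edge(make_edge(leaf, "RO:1", "A:sink", "r"))
        t = compile_template(
            {
                "nodes": [{"id": "A:hub"}, {}, {"id": "A:sink"}],
                "edges": [{}, {}],
            }
        )
        paths = enumerate_paths(g, t)
        summary = summarize_paths(paths, g, template=t)
        assert [(r[1], r[3]) for r in summary.rows] == [
            ("B:x", 1), ("B:y", 1),
        ]

    def test_group_filter_keeps_counts(self):
        g = KnowledgeGraph()
        g.add_node(make_node("GENE:1", SemanticGroup.GENE))
        g.add_node(make_node("DISO:1", SemanticGroup.DISO))
        g.add_edge(make_edge("A:s", "RO:1", "GENE:1", "r"))
        g.add_edge(make_edge("GENE:1", "RO:1", "A:t", "r"))
        g.add_edge(make_edge("A:s", "RO:1", "DISO:1", "r"))
        g.add_edge(make_edge("DISO:1", "RO:1", "A:t", "r"))
        t = compile_template(
            {
                "nodes": [{"id": "A:s"}, {}, {"id": "A:t"}],
                "edges": [{}, {}],
            }
        )
        paths = enumerate_paths(g, t)
        gene_only = summarize_paths(
            paths, g, group_filter=SemanticGroup.GENE, template=t
        )
        assert [(r[1], r[3]) for r in gene_only.rows] == [("GENE:1", 1)]

    def test_mixed_length_rejected(self):
        g, t, paths = self._paths_graph()
        short = enumerate_paths(g, wildcard_template(1))
        with pytest.raises(ValidationError, match="mixed"):
            summarize_paths(list(paths) + list(short), g)

    def test_empty_path_list(self):
        summary = summarize_paths([], KnowledgeGraph())
        assert summary.n_paths == 0 and summary.rows == []
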