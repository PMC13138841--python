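"""Ontology handling: OBO parsing, temporal diffs, true-path propagation,
label partitioning and hierarchical score consistency."""

import networkx as nx
import numpy as np
import pytest

from gofuse.evaluation import ScoreMatrix
from gofuse.ontology import (
    AnnotationTable,
    OboParseError,
    hierarchical_postprocess,
    parse_obo,
    partition_labels,
    propagate_true_path,
    temporal_label_diff,
    write_obo,
)

from conftest import TOY_OBO, random_toy_dag


class TestParseObo:
    def test_three_term_chain(self, chain_graph):
        assert chain_graph.term_ids() == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert set(chain_graph.dag.edges) == {
            ("GO:0000002", "GO:0000001"),
            ("GO:0000003", "GO:0000002"),
        }

    def test_namespace_filtering(self):
        mf = parse_obo(TOY_OBO, "MF")
        assert mf.term_ids() == {"GO:0000009"}

    def test_two_parents_and_part_of(self):
        obo = TOY_OBO + (
            "\n[Term]\nid: GO:0000004\nname: double parent\n"
            "namespace: biological_process\nis_a: GO:0000001\n"
            "relationship: part_of GO:0000002\n"
        )
        g = parse_obo(obo, "BP")
        assert g.dag.out_degree("GO:0000004") == 2
        assert set(g.dag.successors("GO:0000004")) == {"GO:0000001", "GO:0000002"}

    def test_obsolete_term_flagged_and_excluded(self):
        obo = TOY_OBO + (
            "\n[Term]\nid: GO:0000005\nname: gone\n"
            "namespace: biological_process\nis_obsolete: true\n"
            "is_a: GO:0000001\n"
        )
        g = parse_obo(obo, "BP")
        assert g.terms["GO:0000005"].obsolete
        assert "GO:0000005" not in g.dag
        assert g.dag.degree("GO:0000001") == 1  # no edge from the obsolete term

    def test_malformed_stanza_reports_line(self):
        bad = "[Term]\nid: GO:0000001\nnamespace biological_process\n"
        with pytest.raises(OboParseError, match="line 3"):
            parse_obo(bad, "BP")

    def test_cycle_rejected(self):
        obo = (
            "[Term]\nid: GO:0000001\nnamespace: biological_process\nis_a: GO:0000002\n"
            "\n[Term]\nid: GO:0000002\nnamespace: biological_process\nis_a: GO:0000001\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            parse_obo(obo, "BP")

    def test_obo_round_trip(self, chain_graph, tmp_path):
        path = tmp_path / "toy.obo"
        write_obo(chain_graph, path)
        again = parse_obo(path.read_text(), "BP")
        assert again.term_ids() == chain_graph.term_ids()
        assert set(again.dag.edges) == set(chain_graph.dag.edges)


class TestTemporalDiff:
    def test_identical_graphs_empty(self, chain_graph):
        assert temporal_label_diff(chain_graph, chain_graph) == set()

    def test_single_added_term(self, chain_graph):
        new = parse_obo(
            TOY_OBO + "\n[Term]\nid: GO:0000008\nnamespace: biological_process\n",
            "BP",
        )
        assert temporal_label_diff(chain_graph, new) == {"GO:0000008"}

    def test_namespace_mismatch(self, chain_graph):
        mf = parse_obo(TOY_OBO, "MF")
        with pytest.raises(ValueError, match="mismatch"):
            temporal_label_diff(chain_graph, mf)

    def test_randomized_vs_brute_force(self, rng):
        # oracle: plain set difference over id lists
        for _ in range(20):
            old_ids = {f"GO:{i:07d}" for i in rng.choice(60, size=30, replace=False)}
            new_ids = {f"GO:{i:07d}" for i in rng.choice(60, size=30, replace=False)}
            from gofuse.synthetic import _edgeless_graph

            old = _edgeless_graph(sorted(old_ids), "BP", "old")
            new = _edgeless_graph(sorted(new_ids), "BP", "new")
            expected = {t for t in new_ids if t not in old_ids}
            assert temporal_label_diff(old, new) == expected


class TestPropagation:
    def test_leaf_closure_on_chain(self, chain_graph):
        table = AnnotationTable({"P1": {"GO:0000003"}}, "BP")
        out = propagate_true_path(table, chain_graph)
        assert out.annotations["P1"] == {
            "GO:0000001",
            "GO:0000002",
            "GO:0000003",
        }

    def test_root_only_unchanged(self, chain_graph):
        table = AnnotationTable({"P1": {"GO:0000001"}}, "BP")
        out = propagate_true_path(table, chain_graph)
        assert out.annotations == {"P1": {"GO:0000001"}}

    def test_empty_table(self, chain_graph):
        out = propagate_true_path(AnnotationTable({}, "BP"), chain_graph)
        assert out.annotations == {}

    def test_unknown_term_listed(self, chain_graph):
        table = AnnotationTable({"P1": {"GO:9999999"}}, "BP")
        with pytest.raises(KeyError, match="GO:9999999"):
            propagate_true_path(table, chain_graph)

    def test_idempotent_and_matches_transitive_closure(self, rng):
        # 50 random toy DAGs vs a brute-force transitive-closure oracle
        for _ in range(50):
            g, ids = random_toy_dag(rng, int(rng.integers(3, 15)))
            terms = {ids[i] for i in rng.choice(len(ids), size=2, replace=False)}
            table = AnnotationTable({"P1": terms}, "BP")
            once = propagate_true_path(table, g)
            twice = propagate_true_path(once, g)
            assert once.annotations == twice.annotations
            closure = nx.transitive_closure(g.dag)
            expected = set(terms)
            for t in terms:
                expected |= set(closure.successors(t))
            assert once.annotations["P1"] == expected


class TestPartitionLabels:
    def _graphs(self, old_ids, new_ids):
        from gofuse.synthetic import _edgeless_graph

        return (
            _edgeless_graph(sorted(old_ids), "BP", "old"),
            _edgeless_graph(sorted(new_ids), "BP", "new"),
        )

    def test_no_temporal_diff(self):
        old, new = self._graphs({"A", "B", "C"}, {"A", "B", "C"})
        p = partition_labels({"A", "B"}, {"B", "C"}, old, new)
        assert (set(p.shared), set(p.unseen)) == ({"B"}, {"C"})
        assert (set(p.training_only), set(p.zero_shot)) == ({"A"}, set())

    def test_zero_shot_precedence(self):
        old, new = self._graphs({"A", "B"}, {"A", "B", "C"})
        p = partition_labels({"A", "B"}, {"B", "C"}, old, new)
        assert set(p.zero_shot) == {"C"}
        assert set(p.unseen) == set()

    def test_disjoint_train_test(self):
        old, new = self._graphs({"A", "B", "C", "D"}, {"A", "B", "C", "D"})
        p = partition_labels({"A", "B"}, {"C", "D"}, old, new)
        assert set(p.shared) == set()
        assert set(p.unseen) == {"C", "D"}

    def test_train_terms_must_be_in_old(self):
        old, new = self._graphs({"A"}, {"A", "B"})
        with pytest.raises(ValueError, match="missing from the old"):
            partition_labels({"B"}, {"A"}, old, new)

    def test_partition_covers_test_terms_and_is_disjoint(self, rng):
        universe = [f"T{i}" for i in range(20)]
        for _ in range(20):
            new_ids = set(universe)
            old_ids = set(rng.choice(universe, size=14, replace=False))
            train = set(rng.choice(sorted(old_ids), size=8, replace=False))
            test = set(rng.choice(universe, size=10, replace=False))
            old, new = self._graphs(old_ids, new_ids)
            p = partition_labels(train, test, old, new)
            union = set(p.shared) | set(p.unseen) | set(p.zero_shot)
            assert union == test
            total = len(p.shared) + len(p.unseen) + len(p.zero_shot) + len(
                p.training_only
            )
            assert len(union | set(p.training_only)) == total


class TestHierarchicalPostprocess:
    def test_chain_max_over_descendants(self, chain_graph):
        # scores (root, mid, leaf) = (0.1, 0.2, 0.9) -> all 0.9
        scores = ScoreMatrix(
            np.array([[0.1, 0.2, 0.9]]),
            ["P1"],
            ["GO:0000001", "GO:0000002", "GO:0000003"],
        )
        out = hierarchical_postprocess(scores, chain_graph)
        np.testing.assert_allclose(out.values, [[0.9, 0.9, 0.9]])

    def test_consistent_scores_fixed_point(self, chain_graph):
        scores = ScoreMatrix(
            np.array([[0.9, 0.5, 0.2]]),
            ["P1"],
            ["GO:0000001", "GO:0000002", "GO:0000003"],
        )
        out = hierarchical_postprocess(scores, chain_graph)
        np.testing.assert_array_equal(out.values, scores.values)

    def test_single_node_identity(self):
        from gofuse.synthetic import _edgeless_graph

        g = _edgeless_graph(["GO:0000001"], "BP", "v")
        scores = ScoreMatrix(np.array([[0.4]]), ["P1"], ["GO:0000001"])
        out = hierarchical_postprocess(scores, g)
        np.testing.assert_array_equal(out.values, scores.values)

    def test_unknown_column_rejected(self, chain_graph):
        scores = ScoreMatrix(np.array([[0.5]]), ["P1"], ["GO:7777777"])
        with pytest.raises(ValueError, match="GO:7777777"):
            hierarchical_postprocess(scores, chain_graph)

    def test_monotone_and_never_lowered_on_random_dags(self, rng):
        for _ in range(25):
            g, ids = random_toy_dag(rng, int(rng.integers(2, 12)))
            vals = rng.uniform(size=(3, len(ids)))
            scores = ScoreMatrix(vals, ["P1", "P2", "P3"], ids)
            out = hierarchical_postprocess(scores, g)
            assert np.all(out.values >= vals - 1e-15)
            col = {t: j for j, t in enumerate(ids)}
            for child, parent in g.dag.edges:
                assert np.all(
                    out.values[:, col[parent]] >= out.values[:, col[child]]
                )
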