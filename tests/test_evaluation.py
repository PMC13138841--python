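"""Protein-centric Fmax, micro AUPR with tie collapsing, seen/unseen
restrictions and the harmonic mean, each against brute-force oracles."""

import numpy as np
import pytest

from gofuse.evaluation import (
    DEFAULT_GRID,
    ScoreMatrix,
    aupr,
    evaluate,
    fmax,
    harmonic_mean,
    macro_aupr,
    score_all,
    seen_unseen_aupr,
)
from gofuse.io import EmbeddingSet
from gofuse.model import GatedFusionModel, ModelConfig
from gofuse.ontology import AnnotationTable, LabelPartition


def brute_force_aupr(scores, truth):
    """Oracle: explicit enumeration of every distinct threshold."""
    scores = np.asarray(scores, float).ravel()
    truth = np.asarray(truth, bool).ravel()
    n_pos = truth.sum()
    points = []
    for tau in sorted(set(scores), reverse=True):
        pred = scores >= tau
        tp = (pred & truth).sum()
        points.append((tp / pred.sum(), tp / n_pos))
    area, prev_r = 0.0, 0.0
    for p, r in points:
        area += (r - prev_r) * p
        prev_r = r
    return area


def brute_force_fmax(values, y_true, grid):
    """Oracle: per-threshold loops recomputing precision and recall."""
    best = 0.0
    has_truth = y_true.any(axis=1)
    for tau in grid:
        precisions, recalls = [], []
        for i in range(values.shape[0]):
            pred = (values[i] >= tau) & (values[i] > 0)
            if pred.sum():
                precisions.append((pred & y_true[i]).sum() / pred.sum())
            if has_truth[i]:
                recalls.append((pred & y_true[i]).sum() / y_true[i].sum())
        p = np.mean(precisions) if precisions else 0.0
        r = np.mean(recalls) if recalls else 0.0
        if p + r:
            best = max(best, 2 * p * r / (p + r))
    return best


def make_instance(rng, n_prot, n_term):
    values = rng.uniform(size=(n_prot, n_term)).round(2)  # rounding forces ties
    y_true = rng.uniform(size=(n_prot, n_term)) < 0.35
    # every protein gets at least one true term
    for i in range(n_prot):
        if not y_true[i].any():
            y_true[i, rng.integers(n_term)] = True
    proteins = [f"P{i}" for i in range(n_prot)]
    terms = [f"T{j}" for j in range(n_term)]
    truth = AnnotationTable(
        {p: {terms[j] for j in np.flatnonzero(y_true[i])} for i, p in enumerate(proteins)},
        "BP",
    )
    return ScoreMatrix(values, proteins, terms), truth, y_true


class TestAupr:
    def test_perfect_separation(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        y = [1, 0, 0, 1, 0]
        assert aupr([0.4] * 5, y) == pytest.approx(np.mean(y))

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            aupr([0.5, 0.2], [0, 0])

    def test_random_instances_vs_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 31))
            s = rng.uniform(size=n).round(1)
            y = rng.uniform(size=n) < 0.4
            if not y.any():
                y[0] = True
            assert aupr(s, y) == pytest.approx(brute_force_aupr(s, y))

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(20):
            s = rng.uniform(size=50)
            y = rng.uniform(size=50) < 0.3
            if not y.any():
                y[0] = True
            assert aupr(s, y) == pytest.approx(average_precision_score(y, s))

    def test_monotone_transform_invariance(self, rng):
        s = rng.uniform(size=40)
        y = rng.uniform(size=40) < 0.3
        y[0] = True
        assert aupr(s, y) == pytest.approx(aupr(s**3, y))


class TestFmax:
    def test_perfect_ranking_gives_one(self):
        scores = ScoreMatrix(
            np.array([[0.9, 0.8, 0.1], [0.7, 0.1, 0.9]]),
            ["P1", "P2"],
            ["A", "B", "C"],
        )
        truth = AnnotationTable({"P1": {"A", "B"}, "P2": {"A", "C"}}, "BP")
        f, tau, p, r = fmax(scores, truth)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0) and r == pytest.approx(1.0)

    def test_all_zero_scores_give_zero(self):
        scores = ScoreMatrix(np.zeros((2, 3)), ["P1", "P2"], ["A", "B", "C"])
        truth = AnnotationTable({"P1": {"A"}, "P2": {"B"}}, "BP")
        f, _, _, _ = fmax(scores, truth)
        assert f == 0.0

    def test_missing_protein_rejected(self):
        scores = ScoreMatrix(np.array([[0.5]]), ["P1"], ["A"])
        with pytest.raises(KeyError, match="P1"):
            fmax(scores, AnnotationTable({"P2": {"A"}}, "BP"))

    def test_random_instances_vs_exhaustive_sweep(self, rng):
        for _ in range(50):
            scores, truth, y_true = make_instance(
                rng, int(rng.integers(2, 6)), int(rng.integers(2, 7))
            )
            f, tau, p, r = fmax(scores, truth)
            expected = brute_force_fmax(scores.values, y_true, DEFAULT_GRID)
            assert f == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        # rank statistic: squaring scores must not change Fmax (grid refined
        # to hit the transformed thresholds)
        scores, truth, _ = make_instance(rng, 5, 6)
        grid = np.unique(np.concatenate([scores.values.ravel(), [0.0, 1.0]]))
        f1, *_ = fmax(scores, truth, grid)
        squared = ScoreMatrix(scores.values**2, scores.protein_ids, scores.term_ids)
        f2, *_ = fmax(squared, truth, grid**2)
        assert f1 == pytest.approx(f2)


class TestSeenUnseen:
    def _setup(self, rng):
        scores, truth, _ = make_instance(rng, 6, 8)
        terms = scores.term_ids
        partition = LabelPartition(
            shared=frozenset(terms[:4]),
            unseen=frozenset(terms[4:6]),
            training_only=frozenset(),
            zero_shot=frozenset(terms[6:]),
        )
        return scores, truth, partition

    def test_slicing_oracle(self, rng):
        scores, truth, partition = self._setup(rng)
        seen, unseen = seen_unseen_aupr(scores, truth, partition)
        sub_seen = scores.restrict_columns(set(partition.shared))
        sub_unseen = scores.restrict_columns(
            set(partition.unseen | partition.zero_shot)
        )
        assert seen == pytest.approx(
            aupr(sub_seen.values, sub_seen.truth_matrix(truth))
        )
        assert unseen == pytest.approx(
            aupr(sub_unseen.values, sub_unseen.truth_matrix(truth))
        )

    def test_all_shared_makes_unseen_not_applicable(self, rng):
        scores, truth, _ = make_instance(rng, 4, 5)
        partition = LabelPartition(
            shared=frozenset(scores.term_ids),
            unseen=frozenset(),
            training_only=frozenset(),
            zero_shot=frozenset(),
        )
        seen, unseen = seen_unseen_aupr(scores, truth, partition)
        assert unseen is None
        assert seen == pytest.approx(aupr(scores.values, scores.truth_matrix(truth)))

    def test_column_permutation_invariance(self, rng):
        scores, truth, partition = self._setup(rng)
        perm = rng.permutation(len(scores.term_ids))
        shuffled = ScoreMatrix(
            scores.values[:, perm],
            scores.protein_ids,
            [scores.term_ids[j] for j in perm],
        )
        assert seen_unseen_aupr(scores, truth, partition) == pytest.approx(
            seen_unseen_aupr(shuffled, truth, partition)
        )


class TestHarmonicMean:
    def test_printed_reference_pairs(self):
        # published seen/unseen AUPR pairs and their harmonic means (4 d.p.)
        assert round(harmonic_mean(0.5021, 0.2393), 4) == 0.3241
        assert round(harmonic_mean(0.7380, 0.4806), 4) == 0.5821
        assert round(harmonic_mean(0.7733, 0.5862), 4) == 0.6669

    def test_idempotent_on_equal_inputs(self):
        assert harmonic_mean(0.42, 0.42) == pytest.approx(0.42)

    def test_zero_annihilates(self):
        assert harmonic_mean(0.9, 0.0) == 0.0
        assert harmonic_mean(0.0, 0.0) == 0.0

    def test_bounded_by_arithmetic_mean(self, rng):
        for _ in range(50):
            a, b = rng.uniform(size=2)
            assert harmonic_mean(a, b) <= (a + b) / 2 + 1e-12


class TestScoreAllAndEvaluate:
    @pytest.fixture
    def setup(self, rng):
        cfg = ModelConfig(d_seq=5, d_text=7, d_model=6, d_ctx=4, final_hidden=3, seed=8)
        model = GatedFusionModel(cfg)
        proteins = [f"P{i}" for i in range(3)]
        terms = [f"T{j}" for j in range(4)]
        emb = EmbeddingSet(
            seq={p: rng.standard_normal(5) for p in proteins},
            dom={p: rng.standard_normal(7) for p in proteins},
            label={t: rng.standard_normal(7) for t in terms},
        )
        return model, emb, proteins, terms

    def test_batched_equals_per_pair_loop(self, setup):
        from gofuse.pooling import EmbeddingTriple

        model, emb, proteins, terms = setup
        batched = score_all(model, emb, proteins, terms)
        for i, p in enumerate(proteins):
            for j, t in enumerate(terms):
                prob, _ = model.forward(
                    EmbeddingTriple(emb.seq[p], emb.dom[p], emb.label[t])
                )
                assert batched.values[i, j] == pytest.approx(prob, abs=1e-6)

    def test_duplicate_protein_rows_identical(self, setup, rng):
        model, emb, proteins, terms = setup
        emb.seq["P9"], emb.dom["P9"] = emb.seq["P0"], emb.dom["P0"]
        out = score_all(model, emb, ["P0", "P9"], terms)
        np.testing.assert_array_equal(out.values[0], out.values[1])

    def test_repeated_invocation_identical(self, setup):
        model, emb, proteins, terms = setup
        a = score_all(model, emb, proteins, terms)
        b = score_all(model, emb, proteins, terms)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_embedding_names_entity(self, setup):
        model, emb, proteins, terms = setup
        with pytest.raises(KeyError, match="P7"):
            score_all(model, emb, proteins + ["P7"], terms)

    def test_evaluate_composes_components(self, rng):
        scores, truth, _ = make_instance(rng, 5, 6)
        terms = scores.term_ids
        partition = LabelPartition(
            shared=frozenset(terms[:3]),
            unseen=frozenset(terms[3:]),
            training_only=frozenset(),
            zero_shot=frozenset(),
        )
        rep = evaluate(scores, truth, partition)
        f, tau, p, r = fmax(scores, truth)
        assert rep.fmax == pytest.approx(f)
        assert rep.aupr == pytest.approx(
            aupr(scores.values, scores.truth_matrix(truth))
        )
        seen, unseen = seen_unseen_aupr(scores, truth, partition)
        assert rep.seen_aupr == pytest.approx(seen)
        assert rep.unseen_aupr == pytest.approx(unseen)
        assert rep.harmonic_mean_h == pytest.approx(harmonic_mean(seen, unseen))

    def test_perfect_predictor_all_ones(self):
        values = np.array([[0.9, 0.1], [0.1, 0.9]])
        scores = ScoreMatrix(values, ["P1", "P2"], ["A", "B"])
        truth = AnnotationTable({"P1": {"A"}, "P2": {"B"}}, "BP")
        partition = LabelPartition(
            shared=frozenset({"A"}),
            unseen=frozenset({"B"}),
            training_only=frozenset(),
            zero_shot=frozenset(),
        )
        rep = evaluate(scores, truth, partition)
        for metric in (rep.fmax, rep.aupr, rep.seen_aupr, rep.unseen_aupr,
                       rep.harmonic_mean_h):
            assert metric == pytest.approx(1.0)

    def test_macro_aupr_mode(self, rng):
        scores, truth, y_true = make_instance(rng, 6, 5)
        per_term = [
            aupr(scores.values[:, j], y_true[:, j])
            for j in range(5)
            if y_true[:, j].any()
        ]
        assert macro_aupr(scores, truth) == pytest.approx(np.mean(per_term))
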