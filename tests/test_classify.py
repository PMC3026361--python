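"""Annotation, classification, scoring and the new-document classifier."""

import itertools

import numpy as np
import pytest

from faun import (
    FaunClassifier,
    UNASSIGNED,
    UNCLASSIFIABLE,
    auto_annotate,
    classify_new_document,
    classify_strongest,
    correctness,
    evaluate,
    multilabel_assign,
    precision_recall_f1,
    total_correctness,
)
from faun.classify import ClassMap

from test_features import make_model


class TestAutoAnnotate:
    def test_weighted_majority(self):
        # 3 genes of class X (weights 2,2,2) and 1 of class Y (weight 1) pass
        m = make_model(
            W=np.ones((2, 1)), H=[[2.0, 2.0, 2.0, 1.0]],
            doc_ids=["a", "b", "c", "d"],
        )
        classes = {"a": "X", "b": "X", "c": "X", "d": "Y"}
        cmap = auto_annotate(m, classes, f_tau=0.4)
        assert cmap[0] == "X"

    def test_ftau_one_labels_by_argmax_gene(self):
        m = make_model(
            W=np.ones((2, 1)), H=[[1.0, 5.0, 2.0]], doc_ids=["a", "b", "c"]
        )
        cmap = auto_annotate(m, {"a": "X", "b": "Y", "c": "X"}, f_tau=1.0)
        assert cmap[0] == "Y"

    def test_all_zero_feature_unassigned(self):
        m = make_model(
            W=np.ones((2, 2)), H=[[0.0, 0.0], [1.0, 2.0]], doc_ids=["a", "b"]
        )
        cmap = auto_annotate(m, {"a": "X", "b": "Y"}, f_tau=1.0)
        assert cmap[0] == UNASSIGNED
        assert cmap[1] == "Y"

    def test_tie_resolved_by_highest_weight_gene(self):
        # classes X and Y both sum to 3.0; the single heaviest gene is Y
        m = make_model(
            W=np.ones((2, 1)), H=[[3.0, 1.5, 1.5]], doc_ids=["y1", "x1", "x2"]
        )
        cmap = auto_annotate(m, {"y1": "Y", "x1": "X", "x2": "X"}, f_tau=0.4)
        assert cmap[0] == "Y"

    def test_unlabeled_gene_reported(self):
        m = make_model(W=np.ones((2, 1)), H=[[1.0, 2.0]], doc_ids=["a", "b"])
        with pytest.raises(KeyError, match="b"):
            auto_annotate(m, {"a": "X"}, f_tau=0.0)


class TestClassifyStrongest:
    def test_argmax_feature_label(self):
        m = make_model(
            W=np.ones((2, 3)), H=[[0.1, 0.0], [5.0, 0.0], [0.2, 0.0]],
            doc_ids=["g", "z"],
        )
        cmap = ClassMap({0: "A", 1: "Autism", 2: "B"}, "manual")
        assert classify_strongest(m, cmap, "g") == "Autism"

    def test_all_zero_column_unclassifiable(self):
        m = make_model(
            W=np.ones((2, 2)), H=[[1.0, 0.0], [2.0, 0.0]], doc_ids=["g", "z"]
        )
        cmap = ClassMap({0: "A", 1: "B"}, "manual")
        assert classify_strongest(m, cmap, "z") == UNCLASSIFIABLE

    def test_tie_takes_lowest_feature_index(self):
        m = make_model(W=np.ones((2, 3)), H=[[1.0], [2.0], [2.0]], doc_ids=["g"])
        cmap = ClassMap({0: "A", 1: "B", 2: "C"}, "manual")
        assert classify_strongest(m, cmap, "g") == "B"


class TestMultilabel:
    def setup_method(self):
        self.model = make_model(
            W=np.ones((2, 3)),
            H=[[3.0, 1.0, 0.5], [0.5, 2.0, 1.9], [0.0, 0.0, 4.0]],
            doc_ids=["a", "b", "c"],
        )
        self.cmap = ClassMap({0: "A", 1: "B", 2: "A"}, "manual")

    def test_union_of_passed_features(self):
        got = multilabel_assign(self.model, self.cmap, f_tau=0.3)
        assert got["a"] == {"A"}  # passes f0; f1 cutoff 0.6 -> 0.5 fails
        assert got["b"] == {"A", "B"}
        assert got["c"] == {"A", "B"}

    def test_set_semantics_for_duplicate_labels(self):
        got = multilabel_assign(self.model, self.cmap, f_tau=0.0)
        assert got["c"] == {"A", "B"}  # features 0 and 2 both labeled A, counted once

    def test_monotone_in_threshold(self):
        loose = multilabel_assign(self.model, self.cmap, f_tau=0.2)
        tight = multilabel_assign(self.model, self.cmap, f_tau=1.0)
        for g in ("a", "b", "c"):
            assert tight[g] <= loose[g]

    def test_unassigned_features_contribute_nothing(self):
        cmap = ClassMap({0: UNASSIGNED, 1: UNASSIGNED, 2: UNASSIGNED}, "automatic")
        got = multilabel_assign(self.model, cmap, f_tau=0.0)
        assert all(s == frozenset() for s in got.values())


class TestScoring:
    @pytest.mark.parametrize(
        "assigned, truth, expected",
        [({"A"}, "A", 1.0), ({"A", "B"}, "A", 0.5), ({"B", "C"}, "A", 0.0),
         (set(), "A", 0.0), ({"A", "B", "C"}, "B", 1 / 3)],
    )
    def test_correctness(self, assigned, truth, expected):
        assert correctness(assigned, truth) == pytest.approx(expected)

    def test_correctness_exhaustive_enumeration(self):
        """Agrees with brute-force enumeration over all subsets of <= 4 classes."""
        classes = ["A", "B", "C", "D"]
        values = set()
        for r in range(5):
            for subset in itertools.combinations(classes, r):
                for truth in classes:
                    got = correctness(set(subset), truth)
                    want = (1.0 / len(subset)) if truth in subset else 0.0
                    assert got == pytest.approx(want)
                    values.add(round(got, 10))
        assert values == {0.0, 1.0, 0.5, round(1 / 3, 10), 0.25}

    def test_total_correctness(self):
        assert total_correctness([1.0, 0.5, 0.0]) == pytest.approx(50.0)
        assert total_correctness([1.0, 1.0]) == 100.0
        assert total_correctness([0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            total_correctness([])

    def test_f1_reported_worked_example(self):
        # precision 0.69 and recall 0.42 give an F1 that rounds to 0.52
        p, r = 0.69, 0.42
        f1 = 2 * p * r / (p + r)
        assert round(f1, 2) == 0.52
        # and through the set-based route
        p2, r2, f12 = precision_recall_f1({"a", "b"}, {"a", "b"})
        assert (p2, r2, f12) == (1.0, 1.0, 1.0)

    def test_f1_identity_on_random_sets(self):
        rng = np.random.default_rng(30)
        universe = [f"g{i}" for i in range(20)]
        for _ in range(50):
            pred = {g for g in universe if rng.random() < 0.4}
            truth = {g for g in universe if rng.random() < 0.4} or {"g0"}
            p, r, f1 = precision_recall_f1(pred, truth)
            want = 2 * len(pred & truth) / (len(pred) + len(truth)) if pred or truth else 0
            assert f1 == pytest.approx(want)

    def test_disjoint_and_empty_cases(self):
        assert precision_recall_f1({"x"}, {"y"}) == (0.0, 0.0, 0.0)
        assert precision_recall_f1(set(), {"y"}) == (0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            precision_recall_f1({"x"}, set())


class TestClassifyNewDocument:
    def test_document_of_top_term_hits_its_feature(self, synth_model):
        model, gene_classes, docs, truth = synth_model
        from faun import top_terms

        term, _ = top_terms(model, 3, limit=1)[0]
        res = classify_new_document(
            f"{term} " * 5, model.W, model.vocabulary, model.global_weights
        )
        assert res.top_feature == 3
        assert not res.no_signal

    def test_no_overlap_flagged(self, synth_model):
        model, *_ = synth_model
        res = classify_new_document(
            "completely unrelated words here",
            model.W, model.vocabulary, model.global_weights,
        )
        assert res.no_signal
        assert all(s == 0.0 for _, s in res.ranking)

    def test_score_monotone_in_frequency(self, synth_model):
        model, *_ = synth_model
        from faun import top_terms

        term, _ = top_terms(model, 0, limit=1)[0]
        s1 = dict(classify_new_document(
            term, model.W, model.vocabulary, model.global_weights).ranking)
        s2 = dict(classify_new_document(
            f"{term} {term} {term}", model.W, model.vocabulary,
            model.global_weights).ranking)
        for f in s1:
            assert s2[f] >= s1[f] - 1e-12

    def test_strict_thresholds(self, synth_model):
        model, *_ = synth_model
        from faun import top_terms

        term, _ = top_terms(model, 0, limit=1)[0]
        # frequency 1 is not > 1, entropy g is not > g
        idx = model.vocabulary.index()[term]
        res = classify_new_document(
            term, model.W, model.vocabulary, model.global_weights,
            freq_threshold=1,
        )
        assert res.no_signal
        res = classify_new_document(
            term, model.W, model.vocabulary, model.global_weights,
            entropy_threshold=float(model.global_weights[idx]),
        )
        assert res.no_signal


class TestEvaluate:
    def test_perfectly_separated_corpus(self, annotated):
        model, cmap, gene_classes = annotated
        report = evaluate(model, cmap, gene_classes, f_tau=1.0)
        assert report.accuracy_strongest >= 90.0
        assert report.n_genes == len(gene_classes)
        for c, (p, r, f1) in report.per_class.items():
            assert 0 <= p <= 1 and 0 <= r <= 1
            assert f1 == pytest.approx(2 * p * r / (p + r) if p + r else 0.0)

    def test_all_unassigned_map_gives_zero(self, synth_model):
        model, gene_classes, *_ = synth_model
        cmap = ClassMap({f: UNASSIGNED for f in range(model.rank)}, "automatic")
        report = evaluate(model, cmap, gene_classes, f_tau=1.0)
        assert report.accuracy_strongest == 0.0
        assert report.total_correctness == 0.0


def test_sklearn_classifier_in_pipeline(synth_spec):
    """The estimator stack composes as an sklearn pipeline and generalizes."""
    from sklearn.pipeline import Pipeline
    from scipy import sparse

    from faun import (
        LogEntropyTransformer,
        build_count_matrix,
        generate_corpus,
        generate_heldout,
    )
    from faun.corpus import tokenize

    docs, _ = generate_corpus(synth_spec)
    counts = build_count_matrix(docs)
    X = counts.counts.T.tocsr()
    y = [min(d.classes) for d in docs]

    pipe = Pipeline([
        ("weight", LogEntropyTransformer()),
        ("clf", FaunClassifier(n_components=synth_spec.n_topics)),
    ])
    pipe.fit(X, y)
    assert pipe.score(X, y) >= 0.9

    # held-out documents mapped into the training vocabulary
    index = counts.vocabulary.index()
    held = [d for t in range(synth_spec.n_topics)
            for d in generate_heldout(synth_spec, t, 4)]
    rows = sparse.lil_matrix((len(held), X.shape[1]))
    for i, d in enumerate(held):
        for tok in tokenize(d.text):
            j = index.get(tok)
            if j is not None:
                rows[i, j] += 1
    y_held = [min(d.classes) for d in held]
    assert pipe.score(rows.tocsr(), y_held) >= 0.8
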