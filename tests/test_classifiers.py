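import numpy as np
import pytest

from picosense import (
    CLASSIFIER_KINDS,
    ClassifierSpec,
    Element,
    baseline_fit,
    baseline_score,
    train,
)
from picosense.classifiers import score_sentences
from picosense.featurizer import FeatureVector, featurize_dataset, to_arrays


def _fv(**overrides):
    base = dict.fromkeys(
        (
            "pos_abs", "sent_len", "n_punct", "n_num_gt10", "n_num_lt10",
            "title_overlap", "cue_words_P", "cue_words_I", "cue_words_O",
            "cue_verbs_P", "cue_verbs_I", "cue_verbs_O", "mesh_1", "mesh_2",
            "mesh_3", "n_pattern",
        ),
        0,
    )
    base["pos_rel"] = 0.0
    base.update(overrides)
    return FeatureVector(**base)


def _separable_instances(n=40):
    # positives carry cue counts, negatives do not
    pos = [(_fv(cue_words_P=3, cue_verbs_P=2, n_num_gt10=1), 1) for _ in range(n // 4)]
    neg = [(_fv(pos_abs=i % 7, pos_rel=min(1.0, (i % 7) / 6)), 0) for i in range(n)]
    return pos + neg


@pytest.fixture(scope="module")
def synth_instances(small_corpus, cues, sems):
    data = small_corpus["datasets"][Element.P]
    split = int(0.7 * len(data))
    train_inst = featurize_dataset(data[:split], Element.P, cues, sems)
    test = data[split:]
    return train_inst, test


class TestTrainContract:
    def test_separable_toy_perfect_training_accuracy(self):
        inst = _separable_instances()
        model = train(ClassifierSpec("decision_tree", seed=0), inst)
        X, y = to_arrays(inst)
        scores, decisions = score_sentences(model, X)
        assert (decisions == y).all()

    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_same_spec_seed_data_identical_predictions(self, kind):
        inst = _separable_instances()
        X, _ = to_arrays(inst)
        s1, _ = score_sentences(train(ClassifierSpec(kind, seed=7), inst), X)
        s2, _ = score_sentences(train(ClassifierSpec(kind, seed=7), inst), X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_input_rejected(self):
        inst = [(_fv(), 0) for _ in range(10)]
        with pytest.raises(ValueError, match="single class"):
            train(ClassifierSpec("naive_bayes"), inst)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier kind"):
            ClassifierSpec("gradient_boosting")

    def test_schema_mismatch_rejected(self):
        model = train(ClassifierSpec("naive_bayes"), _separable_instances())
        with pytest.raises(ValueError, match="schema"):
            model.score(np.zeros((3, 5)))


class TestScoreContract:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_scores_in_unit_interval(self, kind):
        inst = _separable_instances()
        model = train(ClassifierSpec(kind, seed=3), inst)
        X, _ = to_arrays(inst)
        scores, decisions = score_sentences(model, X)
        assert (scores >= 0).all() and (scores <= 1).all()
        assert set(np.unique(decisions)) <= {0, 1}

    def test_identical_sentences_identical_scores(self):
        inst = _separable_instances()
        model = train(ClassifierSpec("mlp", seed=1), inst)
        X = np.stack([_fv(cue_words_P=2).as_array()] * 4)
        scores, _ = score_sentences(model, X)
        assert len(set(scores.tolist())) == 1

    def test_svm_binary_mode_scores_are_exactly_zero_or_one(self, synth_instances):
        train_inst, _ = synth_instances
        model = train(ClassifierSpec("svm_rbf", seed=2), train_inst)
        X, _ = to_arrays(train_inst)
        scores, _ = score_sentences(model, X)
        assert set(np.unique(scores)) <= {0.0, 1.0}

    def test_probabilistic_learners_emit_intermediate_scores(self, synth_instances):
        train_inst, _ = synth_instances
        X, _ = to_arrays(train_inst)
        for kind in ("naive_bayes", "random_forest", "mlp"):
            scores, _ = score_sentences(train(ClassifierSpec(kind, seed=2), train_inst), X)
            assert ((scores > 0) & (scores < 1)).any()

    def test_mlp_learns_synthetic_population_signal(self, synth_instances, cues, sems):
        """With strong cue signal the MLP separates gold sentences well on
        held-out abstracts (sentence-level f-measure above 0.8)."""
        train_inst, test = synth_instances
        model = train(ClassifierSpec("mlp", seed=5), train_inst)
        test_inst = featurize_dataset(test, Element.P, cues, sems)
        X, y = to_arrays(test_inst)
        _, decisions = score_sentences(model, X)
        tp = int(((decisions == 1) & (y == 1)).sum())
        fp = int(((decisions == 1) & (y == 0)).sum())
        fn = int(((decisions == 0) & (y == 1)).sum())
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        assert 2 * p * r / (p + r) > 0.8


class TestPositionBaseline:
    def test_stored_median_selects_nearest_sentence(self):
        from picosense.classifiers import PositionBaseline

        model = PositionBaseline(Element.P, 0.30)
        scores, decisions = baseline_score(model, 11)
        assert decisions.sum() == 1
        assert int(np.argmax(scores)) == 3  # pos_rel 3/10 = 0.3 exactly

    def test_single_sentence_abstract_selected(self):
        from picosense.classifiers import PositionBaseline

        scores, decisions = baseline_score(PositionBaseline(Element.O, 0.9), 1)
        assert scores.tolist() == [1.0]

    def test_fit_requires_gold_and_data(self, small_corpus):
        with pytest.raises(ValueError, match="empty"):
            baseline_fit([], Element.P)
        model = baseline_fit(small_corpus["datasets"][Element.P], Element.P)
        assert 0.0 <= model.median_pos_rel <= 1.0

    def test_exactly_one_prediction_per_abstract(self, small_corpus):
        model = baseline_fit(small_corpus["datasets"][Element.P], Element.P)
        for la in small_corpus["datasets"][Element.P]:
            _, decisions = baseline_score(model, len(la.abstract))
            assert decisions.sum() == 1
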