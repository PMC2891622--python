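"""Uniform train/score contract over the base learners and the position
baseline.

Five feature-based learners are supported — a single decision tree, naive
Bayes, a random forest, an RBF-kernel support vector machine, and a
multi-layer perceptron — plus a relative-position baseline that always
labels exactly one sentence per abstract (the one whose relative position
is nearest the median gold position seen in training).

Every model scores a sentence in [0, 1] and emits a binary decision.  The
SVM is binary-scored by default: its raw class prediction is the score, so
it can never rank two sentences of an abstract apart — a deliberate
reproduction of the behaviour margin-based classifiers show in this
pipeline.  A calibrated-probability mode (Platt scaling) is available via
``hyperparameters={"probability": True}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .abstract_model import Element, LabeledAbstract
from .featurizer import FEATURE_NAMES, FeatureVector, to_arrays

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "Model",
    "train",
    "score_sentences",
    "PositionBaseline",
    "baseline_fit",
    "baseline_score",
]

#: Fixed classifier order used by fusion weight vectors and reports.
CLASSIFIER_KINDS: tuple[str, ...] = (
    "decision_tree",
    "naive_bayes",
    "random_forest",
    "svm_rbf",
    "mlp",
)

#: Decision threshold for probabilistic learners.
DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS + ("position_baseline",):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    hp.pop("probability", None)
    class_weight = "balanced" if hp.pop("balanced", False) else None
    if spec.kind == "decision_tree":
        return DecisionTreeClassifier(
            random_state=spec.seed, class_weight=class_weight, **hp
        )
    if spec.kind == "naive_bayes":
        return GaussianNB(**hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(
            random_state=spec.seed, class_weight=class_weight, **hp
        )
    if spec.kind == "svm_rbf":
        # "radial kernel"; C and gamma at toolkit-conventional defaults.
        hp.setdefault("C", 1.0)
        hp.setdefault("gamma", "scale")
        svc = SVC(
            kernel="rbf", random_state=spec.seed, class_weight=class_weight, **hp
        )
        if spec.hyperparameters.get("probability", False):
            # Platt-calibrated probability mode, off by default
            from sklearn.calibration import CalibratedClassifierCV

            svc = CalibratedClassifierCV(svc, ensemble=False)
        return make_pipeline(StandardScaler(), svc)
    if spec.kind == "mlp":
        # one hidden layer of ceil((n_features + 2) / 2) units
        hp.setdefault("hidden_layer_sizes", ((len(FEATURE_NAMES) + 2 + 1) // 2,))
        hp.setdefault("max_iter", 150)
        mlp = MLPClassifier(random_state=spec.seed, **hp)
        return make_pipeline(StandardScaler(), mlp)
    raise ValueError(f"no estimator for kind {spec.kind!r}")


@dataclass
class Model:
    """A trained scorer: maps feature matrices to scores in [0, 1]."""

    spec: ClassifierSpec
    estimator: object
    n_features: int = len(FEATURE_NAMES)

    @property
    def binary_scores(self) -> bool:
        return self.spec.kind == "svm_rbf" and not self.spec.hyperparameters.get(
            "probability", False
        )

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature schema mismatch: expected (*, {self.n_features}), got {X.shape}"
            )
        if self.binary_scores:
            return self.estimator.predict(X).astype(np.float64)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def decide(self, scores: np.ndarray) -> np.ndarray:
        return (scores >= DECISION_THRESHOLD).astype(int)


def train(
    spec: ClassifierSpec, instances: Sequence[tuple[FeatureVector, int]]
) -> Model:
    """Fit one base learner on (vector, label) instances.

    Requires at least one positive and one negative instance; training is
    deterministic given the spec's seed.
    """
    X, y = to_arrays(instances)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    est = _build_estimator(spec)
    est.fit(X, y)
    return Model(spec, est)


def score_sentences(
    model: Model, sentence_features: Sequence[FeatureVector] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score one abstract's sentences: returns (scores, decisions)."""
    if isinstance(sentence_features, np.ndarray):
        X = sentence_features
    else:
        X = np.stack([fv.as_array() for fv in sentence_features])
    scores = model.score(X)
    return scores, model.decide(scores)


# ---------------------------------------------------------------------------
# Position baseline
# ---------------------------------------------------------------------------


@dataclass
class PositionBaseline:
    """Predicts the sentence nearest a stored median relative position."""

    element: Element
    median_pos_rel: float


def baseline_fit(dataset: Sequence[LabeledAbstract], element: Element) -> PositionBaseline:
    """Store the median relative position of the gold sentences."""
    positions = []
    for la in dataset:
        if element not in la.gold:
            raise ValueError(f"abstract {la.pmid} has no gold sentence for {element}")
        n = len(la.abstract)
        positions.append(la.gold[element] / (n - 1) if n > 1 else 0.0)
    if not positions:
        raise ValueError("empty dataset")
    return PositionBaseline(element, float(np.median(positions)))


def baseline_score(model: PositionBaseline, n_sentences: int) -> tuple[np.ndarray, np.ndarray]:
    """One-hot scores: exactly one sentence (nearest the stored median
    relative position; ties to the lower index) gets score and decision 1."""
    if n_sentences < 1:
        raise ValueError("abstract has no sentences")
    if n_sentences == 1:
        rel = np.array([0.0])
    else:
        rel = np.arange(n_sentences) / (n_sentences - 1)
    pick = int(np.argmin(np.abs(rel - model.median_pos_rel)))
    scores = np.zeros(n_sentences)
    scores[pick] = 1.0
    return scores, scores.astype(int)
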