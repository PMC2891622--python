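"""Decoding, precision/recall/f-measure, and k-fold cross-validation.

A trained model scores every sentence of an abstract; a decoder turns the
scores into a prediction.  Two decoding modes exist:

``single``
    Predict the top-scoring sentence if its decision criterion fires
    (binary decision for base classifiers, combined score >= 0.5 for the
    linear fusers, a strict majority for the voting fuser); otherwise
    abstain.  Abstention is the mechanism by which precision and recall
    diverge.
``nbest``
    Predict the n highest-scoring sentences (fewer when the abstract is
    shorter), ties broken by the lower sentence index.  Used for the
    multi-sentence Outcome element at cut-offs of two and three.

A prediction is correct iff a predicted sentence index equals the gold
index.  Metrics are micro-averaged over abstracts; a model that always
predicts exactly one sentence per abstract (the position baseline) has
precision = recall = f-measure by construction.

Cross-validation partitions at the abstract level.  Within each fold, the
rank weights of the f-measure-weighted fuser are derived from a held-out
slice of the training portion only, never from test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abstract_model import Element, LabeledAbstract
from .classifiers import (
    CLASSIFIER_KINDS,
    ClassifierSpec,
    Model,
    baseline_fit,
    baseline_score,
)
from .featurizer import featurize, to_arrays
from .fusion import ScoreMatrix, fuse_linear, fuse_vote, rank_weights
from .lexicons import CueLexicon, SemanticLexicon, default_cues, default_semantic

__all__ = [
    "Prediction",
    "MetricRow",
    "EvalReport",
    "CVConfig",
    "decode",
    "score_predictions",
    "cross_validate",
    "FUSION_METHODS",
]

FUSION_METHODS: tuple[str, ...] = ("F1", "F2", "F3")


@dataclass(frozen=True)
class Prediction:
    """Predicted sentence indices (possibly empty) for one abstract/element."""

    pmid: str
    element: Element
    indices: tuple[int, ...]
    scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError(f"duplicate predicted indices for {self.pmid}")


@dataclass
class MetricRow:
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation at the abstract level.

    ``repeats`` > 1 re-partitions the data that many times and averages
    over all rounds (repeated CV)."""

    k: int = 10
    seed: int = 0
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def decode(
    scores: np.ndarray,
    mode: str = "single",
    n: int = 1,
    threshold: float = 0.5,
    decisions: np.ndarray | None = None,
) -> tuple[int, ...]:
    """Turn one abstract's combined scores into predicted sentence indices.

    In single mode the argmax sentence is predicted iff its decision fires
    (its ``decisions`` entry when given, else score >= threshold); nbest
    mode always predicts the top n, ties to the lower index.
    """
    if n < 1:
        raise ValueError("cut-off n must be >= 1")
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if mode == "single":
        best = int(np.argmax(scores))  # first max wins ties
        fires = decisions[best] == 1 if decisions is not None else scores[best] >= threshold
        return (best,) if fires else ()
    if mode == "nbest":
        order = np.argsort(-scores, kind="stable")
        # zero-scored sentences are indistinguishable rejects, never ranked:
        # this is what keeps a binary scorer constant across cut-offs
        return tuple(int(i) for i in order[:n] if scores[i] > 0)
    raise ValueError(f"unknown decode mode {mode!r}")


def score_predictions(
    predictions: Sequence[Prediction], gold: Mapping[str, int]
) -> MetricRow:
    """Micro-averaged precision/recall/f over abstracts.

    TP counts predicted indices equal to the gold index, FP the rest, FN
    the gold sentences never predicted.  Precision is defined as 0 when
    there are no predictions at all (total abstention is penalized).
    """
    by_pmid: dict[str, set[int]] = {}
    n_pred = 0
    for p in predictions:
        if p.pmid not in gold:
            raise ValueError(f"prediction for unknown pmid {p.pmid}")
        by_pmid.setdefault(p.pmid, set()).update(p.indices)
        n_pred += len(p.indices)
    tp = sum(1 for pmid, g in gold.items() if g in by_pmid.get(pmid, ()))
    fp = n_pred - tp
    fn = len(gold) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    # micro-f from counts: identical to 2pr/(p+r) but exact when fp == fn,
    # so a one-prediction-per-abstract decoder has p = r = f to the bit
    f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return MetricRow(precision, recall, f, tp, fp, fn)


@dataclass
class EvalReport:
    """Mean p/r/f per (method, cut-off) with pooled error counts."""

    element: Element
    rows: dict[tuple[str, int], MetricRow] = field(default_factory=dict)

    def f(self, method: str, cutoff: int = 1) -> float:
        return self.rows[(method, cutoff)].f_measure

    def recall(self, method: str, cutoff: int = 1) -> float:
        return self.rows[(method, cutoff)].recall

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "element": self.element.value,
                "method": m,
                "cutoff": n,
                "precision": r.precision,
                "recall": r.recall,
                "f_measure": r.f_measure,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
            }
            for (m, n), r in sorted(self.rows.items())
        ]
        return pd.DataFrame.from_records(recs)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _precompute_features(
    dataset: Sequence[LabeledAbstract],
    cues: CueLexicon,
    sems: SemanticLexicon,
) -> list[np.ndarray]:
    """Per-abstract (S, 17) feature matrices; features are fold-independent."""
    out = []
    for la in dataset:
        X, _ = to_arrays(
            [(featurize(s, la.abstract, cues, sems), 0) for s in la.abstract.sentences]
        )
        out.append(X)
    return out


def _batch_scores(
    model: Model, feats: Sequence[np.ndarray], idx: np.ndarray
) -> list[np.ndarray]:
    """Score many abstracts in one estimator call, then split per abstract."""
    X = np.concatenate([feats[i] for i in idx])
    all_scores = model.score(X)
    sizes = [feats[i].shape[0] for i in idx]
    return np.split(all_scores, np.cumsum(sizes)[:-1])


def _method_predictions(
    dataset: Sequence[LabeledAbstract],
    element: Element,
    idx: np.ndarray,
    base_scores: dict[str, list[np.ndarray]],
    models: dict[str, Model],
    baseline,
    classifiers: Sequence[str],
    fusions: Sequence[str],
    f3_weights: np.ndarray | None,
    cutoffs: Sequence[int],
) -> dict[tuple[str, int], list[Prediction]]:
    preds: dict[tuple[str, int], list[Prediction]] = {}

    def add(method: str, n: int, pmid: str, indices: tuple[int, ...]) -> None:
        preds.setdefault((method, n), []).append(Prediction(pmid, element, indices))

    uniform = np.ones(len(classifiers))
    for pos, i in enumerate(idx):
        la = dataset[i]
        pmid = la.pmid
        rows = np.stack([base_scores[kind][pos] for kind in classifiers])
        decisions = np.stack(
            [models[kind].decide(base_scores[kind][pos]) for kind in classifiers]
        )
        matrix = ScoreMatrix(tuple(classifiers), rows, decisions)
        for n in cutoffs:
            for kind in classifiers:
                s, d = rows[classifiers.index(kind)], decisions[classifiers.index(kind)]
                if n == 1:
                    add(kind, n, pmid, decode(s, "single", decisions=d))
                else:
                    add(kind, n, pmid, decode(s, "nbest", n=n))
            if baseline is not None:
                bs, bd = baseline_score(baseline, len(la.abstract))
                if n == 1:
                    add("BL", n, pmid, decode(bs, "single", decisions=bd))
                else:
                    add("BL", n, pmid, decode(bs, "nbest", n=n))
            if "F1" in fusions:
                fused = fuse_vote(matrix)
                if n == 1:
                    add("F1", n, pmid, () if fused.selected is None else (fused.selected,))
                else:
                    add("F1", n, pmid, decode(fused.combined, "nbest", n=n))
            if "F2" in fusions:
                combined = fuse_linear(matrix, uniform)
                mode = "single" if n == 1 else "nbest"
                add("F2", n, pmid, decode(combined, mode, n=n))
            if "F3" in fusions and f3_weights is not None:
                combined = fuse_linear(matrix, f3_weights)
                mode = "single" if n == 1 else "nbest"
                add("F3", n, pmid, decode(combined, mode, n=n))
    return preds


def cross_validate(
    dataset: Sequence[LabeledAbstract],
    element: Element,
    classifiers: Sequence[str] = CLASSIFIER_KINDS,
    fusions: Sequence[str] = FUSION_METHODS,
    cutoffs: Sequence[int] = (1,),
    cv: CVConfig = CVConfig(),
    cues: CueLexicon | None = None,
    sems: SemanticLexicon | None = None,
    include_baseline: bool = True,
) -> EvalReport:
    """k-fold cross-validated evaluation of base classifiers and fusers.

    The data is partitioned at the abstract level into k near-equal folds
    by a seeded shuffle; each fold serves once as the test set.  Base
    models are fitted on 90% of each training portion; the remaining 10%
    provides the f-measure ranking that fixes the rank-weighted fuser's
    weights for that fold (test data never informs the weights).  Reported
    metrics are the mean over all folds (and repeats).
    """
    dataset = list(dataset)
    if len(dataset) < cv.k:
        raise ValueError(f"dataset has {len(dataset)} abstracts, fewer than k={cv.k}")
    for la in dataset:
        if element not in la.gold:
            raise ValueError(f"abstract {la.pmid} has no gold sentence for {element}")
    cues = cues or default_cues()
    sems = sems or default_semantic()
    classifiers = list(classifiers)
    feats = _precompute_features(dataset, cues, sems)
    labels = [
        np.array(
            [int(s.index == la.gold[element]) for s in la.abstract.sentences], dtype=int
        )
        for la in dataset
    ]
    gold_all = {la.pmid: la.gold[element] for la in dataset}

    fold_rows: dict[tuple[str, int], list[MetricRow]] = {}
    ss = np.random.SeedSequence(cv.seed)
    for repeat in range(cv.repeats):
        rng = np.random.default_rng(ss.spawn(1)[0])
        perm = rng.permutation(len(dataset))
        folds = np.array_split(perm, cv.k)
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.concatenate(
                [f for j, f in enumerate(folds) if j != fold_id]
            )
            # inner 90/10 split of the training portion for weight ranking
            inner = rng.permutation(train_idx)
            n_rank = max(1, len(inner) // 10)
            rank_idx, fit_idx = inner[:n_rank], inner[n_rank:]

            X_fit = np.concatenate([feats[i] for i in fit_idx])
            y_fit = np.concatenate([labels[i] for i in fit_idx])
            clf_seed = int(rng.integers(0, 2**31 - 1))
            models: dict[str, Model] = {
                kind: _train_arrays(ClassifierSpec(kind, seed=clf_seed), X_fit, y_fit)
                for kind in classifiers
            }
            baseline = (
                baseline_fit([dataset[i] for i in fit_idx], element)
                if include_baseline
                else None
            )

            f3_weights = None
            if "F3" in fusions:
                rank_scores = {
                    kind: _batch_scores(models[kind], feats, rank_idx)
                    for kind in classifiers
                }
                f_by_clf = {}
                gold_rank = {dataset[i].pmid: gold_all[dataset[i].pmid] for i in rank_idx}
                for kind in classifiers:
                    preds = []
                    for pos, i in enumerate(rank_idx):
                        s = rank_scores[kind][pos]
                        d = models[kind].decide(s)
                        preds.append(
                            Prediction(
                                dataset[i].pmid,
                                element,
                                decode(s, "single", decisions=d),
                            )
                        )
                    f_by_clf[kind] = score_predictions(preds, gold_rank).f_measure
                f3_weights = rank_weights(f_by_clf, classifiers)

            test_scores = {
                kind: _batch_scores(models[kind], feats, test_idx)
                for kind in classifiers
            }
            preds = _method_predictions(
                dataset,
                element,
                test_idx,
                test_scores,
                models,
                baseline,
                classifiers,
                fusions,
                f3_weights,
                cutoffs,
            )
            gold_fold = {dataset[i].pmid: gold_all[dataset[i].pmid] for i in test_idx}
            for key, plist in preds.items():
                fold_rows.setdefault(key, []).append(score_predictions(plist, gold_fold))

    report = EvalReport(element)
    for key, rows in fold_rows.items():
        report.rows[key] = MetricRow(
            precision=float(np.mean([r.precision for r in rows])),
            recall=float(np.mean([r.recall for r in rows])),
            f_measure=float(np.mean([r.f_measure for r in rows])),
            tp=sum(r.tp for r in rows),
            fp=sum(r.fp for r in rows),
            fn=sum(r.fn for r in rows),
        )
    return report


def _train_arrays(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray) -> Model:
    """Array-level twin of :func:`picosense.classifiers.train`."""
    from .classifiers import _build_estimator

    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    est = _build_estimator(spec)
    est.fit(X, y)
    return Model(spec, est)
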