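"""Score fusion across base classifiers.

Three strategies combine the per-sentence predictions of the base
classifiers for one abstract:

* majority voting — a sentence is a candidate when a strict majority of
  classifiers labels it; ambiguity between candidates is resolved by the
  larger mean prediction score, and the fuser abstains when no sentence
  reaches a majority;
* equi-probable linear combination — the plain mean of the scores;
* rank-weighted linear combination — weights fixed by the observed
  f-measure ranking of the base classifiers (best of K gets weight K,
  next K-1, ..., worst 1), per element.

Weight vectors are kept unnormalized and normalized to sum 1 at use, so
fusion is invariant under positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = ["ScoreMatrix", "FusedResult", "fuse_vote", "fuse_linear", "rank_weights"]


@dataclass
class ScoreMatrix:
    """Per-abstract predictions: classifiers x sentences scores in [0, 1]
    plus per-cell binary decisions, rows in a fixed classifier order."""

    classifiers: tuple[str, ...]
    scores: np.ndarray  # (C, S)
    decisions: np.ndarray  # (C, S)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.decisions = np.asarray(self.decisions, dtype=int)
        if self.scores.shape != self.decisions.shape or self.scores.ndim != 2:
            raise ValueError("scores and decisions must be matching 2-D arrays")
        if self.scores.shape[0] != len(self.classifiers):
            raise ValueError("one row per classifier required")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n_sentences(self) -> int:
        return self.scores.shape[1]


@dataclass
class FusedResult:
    """Combined per-sentence scores and the selected sentence (None when
    the fuser abstains)."""

    combined: np.ndarray
    selected: int | None


def fuse_vote(matrix: ScoreMatrix) -> FusedResult:
    """Majority voting over binary decisions (strict majority: > C/2).

    Among multiple candidates the one with the larger mean score wins,
    ties to the lower sentence index; with no candidate the fuser
    abstains.  The combined score ranks sentences by vote count first and
    mean score second, mapped into [0, 1].
    """
    C = len(matrix.classifiers)
    if C < 3:
        raise ValueError("voting needs at least 3 classifiers")
    votes = matrix.decisions.sum(axis=0)
    mean_scores = matrix.scores.mean(axis=0)
    # lexicographic (votes, mean score) collapsed to one scalar in [0, 1]
    combined = (votes + mean_scores) / (C + 1)
    candidates = np.flatnonzero(votes > C / 2)
    if candidates.size == 0:
        return FusedResult(combined, None)
    best = candidates[int(np.argmax(mean_scores[candidates]))]
    return FusedResult(combined, int(best))


def fuse_linear(matrix: ScoreMatrix, weights: Sequence[float]) -> np.ndarray:
    """Weighted linear combination of prediction scores.

    Weights must be non-negative with a positive sum; they are normalized
    to sum 1, so the output stays in [0, 1] and equal weights reduce to
    the arithmetic mean of the classifier scores.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (len(matrix.classifiers),):
        raise ValueError(
            f"expected {len(matrix.classifiers)} weights, got shape {w.shape}"
        )
    if np.any(w < 0) or not np.isfinite(w).all():
        raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    return (w / total) @ matrix.scores


def rank_weights(
    f_scores: Mapping[str, float], order: Sequence[str]
) -> np.ndarray:
    """Derive rank weights from observed f-measures.

    The best of K classifiers gets weight K, the next K-1, down to 1 for
    the worst; exact ties receive the mean of the tied ranks.  The vector
    is aligned to ``order``.
    """
    f = np.array([f_scores[name] for name in order], dtype=np.float64)
    # rankdata averages ties; rank 1 = smallest f = weight 1
    return rankdata(f, method="average")
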