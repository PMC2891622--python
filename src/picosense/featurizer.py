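"""Fixed-order feature extraction for sentence classification.

Each sentence, in the context of its abstract, maps to a 17-dimensional
vector mixing statistical features (position, length, punctuation, numeric
tokens, title overlap) with knowledge-based features (cue-word/cue-verb
counts per element, semantic-list match counts, explicit sample-size
patterns).  No bag-of-words, no part-of-speech tags: the scheme is
deliberately shallow so preprocessing errors cannot propagate.

The vector layout is immutable; ``FEATURE_NAMES`` is the single source of
truth for the order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .abstract_model import Abstract, Element, LabeledAbstract, Sentence
from .lexicons import CueLexicon, SemanticLexicon, canonical_tokens, count_matches

__all__ = ["FEATURE_NAMES", "FeatureVector", "featurize", "featurize_dataset", "to_arrays"]

FEATURE_NAMES: tuple[str, ...] = (
    "pos_abs",
    "pos_rel",
    "sent_len",
    "n_punct",
    "n_num_gt10",
    "n_num_lt10",
    "title_overlap",
    "cue_words_P",
    "cue_words_I",
    "cue_words_O",
    "cue_verbs_P",
    "cue_verbs_I",
    "cue_verbs_O",
    "mesh_1",
    "mesh_2",
    "mesh_3",
    "n_pattern",
)

# Punctuation marks counted by n_punct; includes both ASCII hyphen-minus
# and the typographic minus sign seen in journal text.
_PUNCT = set(',;:.!?()[]"\'%/-−')

_NUMERIC = re.compile(r"\d+(?:\.\d+)?")
_N_EQ = re.compile(r"\(\s*[nN]\s*=\s*\d+\s*\)")

# Stopwords excluded from the title-overlap count (canonicalized at import).
_STOPWORDS_RAW = """
a an the of in on at by for to with and or but nor not no as is are was were
be been being has have had do does did this that these those it its their our
we they he she you i from than then so such per each all any both more most
other some only also may can could will would should into during after before
between over under about against among through
""".split()


@dataclass(frozen=True)
class FeatureVector:
    """One sentence's descriptor; field order mirrors ``FEATURE_NAMES``."""

    pos_abs: int
    pos_rel: float
    sent_len: int
    n_punct: int
    n_num_gt10: int
    n_num_lt10: int
    title_overlap: int
    cue_words_P: int
    cue_words_I: int
    cue_words_O: int
    cue_verbs_P: int
    cue_verbs_I: int
    cue_verbs_O: int
    mesh_1: int
    mesh_2: int
    mesh_3: int
    n_pattern: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pos_rel <= 1.0:
            raise ValueError(f"pos_rel {self.pos_rel} outside [0, 1]")
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"feature {name} = {v} not finite and non-negative")


def _canonical_stopwords() -> frozenset[str]:
    from .lexicons import canonicalize

    return frozenset(canonicalize(w) for w in _STOPWORDS_RAW)


_STOPWORDS = _canonical_stopwords()


def _cue_terms(words: frozenset[str]) -> list[tuple[str, ...]]:
    return [tuple(w.split(" ")) for w in words]


def featurize(
    sentence: Sentence,
    abstract: Abstract,
    cues: CueLexicon,
    sems: SemanticLexicon,
) -> FeatureVector:
    """Compute the feature vector of one sentence in its abstract context.

    Pure function of (sentence, abstract, lexicons).  Expects headings to
    have been stripped beforehand, otherwise heading words bias the cue
    counts.  Numeric tokens equal to exactly 10 fall in neither bin.
    """
    n = len(abstract)
    if not 0 <= sentence.index < n or abstract.sentences[sentence.index].text != sentence.text:
        raise ValueError(f"sentence {sentence.index} does not belong to abstract {abstract.pmid}")
    text = sentence.text
    tokens = canonical_tokens(text)
    word_tokens = [t for t in tokens if t.isalnum() or "-" in t or "'" in t]

    n_gt10 = n_lt10 = 0
    for t in tokens:
        if _NUMERIC.fullmatch(t):
            v = float(t)
            if v > 10:
                n_gt10 += 1
            elif v < 10:
                n_lt10 += 1

    title_tokens = set(canonical_tokens(abstract.title)) - _STOPWORDS
    overlap = len((set(word_tokens) - _STOPWORDS) & title_tokens)

    cue_w = {
        e: count_matches(word_tokens, _cue_terms(cues.words_for(e))) for e in Element
    }
    cue_v = {
        e: count_matches(word_tokens, _cue_terms(cues.verbs_for(e))) for e in Element
    }
    mesh = {k: count_matches(word_tokens, sems.list_terms(k)) for k in (1, 2, 3)}

    return FeatureVector(
        pos_abs=sentence.index,
        pos_rel=sentence.index / (n - 1) if n > 1 else 0.0,
        sent_len=len(word_tokens),
        n_punct=sum(1 for ch in text if ch in _PUNCT),
        n_num_gt10=n_gt10,
        n_num_lt10=n_lt10,
        title_overlap=overlap,
        cue_words_P=cue_w[Element.P],
        cue_words_I=cue_w[Element.I],
        cue_words_O=cue_w[Element.O],
        cue_verbs_P=cue_v[Element.P],
        cue_verbs_I=cue_v[Element.I],
        cue_verbs_O=cue_v[Element.O],
        mesh_1=mesh[1],
        mesh_2=mesh[2],
        mesh_3=mesh[3],
        n_pattern=len(_N_EQ.findall(text)),
    )


def featurize_dataset(
    dataset: Sequence[LabeledAbstract],
    element: Element,
    cues: CueLexicon,
    sems: SemanticLexicon,
) -> list[tuple[FeatureVector, int]]:
    """Convert a labeled dataset into (vector, binary label) instances.

    One instance per sentence of every abstract, in abstract order then
    sentence order; the label is 1 iff the sentence is the gold sentence
    for ``element``.  Every abstract must carry a gold index for the
    element.
    """
    out: list[tuple[FeatureVector, int]] = []
    for la in dataset:
        if element not in la.gold:
            raise ValueError(f"abstract {la.pmid} has no gold sentence for {element}")
        g = la.gold[element]
        for sent in la.abstract.sentences:
            out.append((featurize(sent, la.abstract, cues, sems), int(sent.index == g)))
    return out


def to_arrays(instances: Sequence[tuple[FeatureVector, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Stack (vector, label) instances into X (n, 17) and y (n,) arrays."""
    if not instances:
        return np.empty((0, len(FEATURE_NAMES))), np.empty((0,), dtype=int)
    X = np.stack([fv.as_array() for fv, _ in instances])
    y = np.array([lab for _, lab in instances], dtype=int)
    return X, y
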