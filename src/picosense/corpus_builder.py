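"""Distant-supervision corpus construction from structured abstracts.

Many clinical-trial abstracts carry author-written section headings
("PARTICIPANTS:", "INTERVENTION:", "MAIN OUTCOME MEASURES:").  These
structural markers let large training corpora be labeled without human
annotation: the first sentence following a distinctive PICO heading is
taken as the gold sentence for that element, I and C merge into a single
exposure element, and at most one sentence is labeled per element — a
deliberately conservative rule, because labeling everything under a
heading imports far too many false positives.

After labeling, all headings (PICO and non-PICO alike) are stripped so the
classifiers train and evaluate on text that looks unstructured, avoiding
trivially biased lexical features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .abstract_model import Abstract, Element, LabeledAbstract, Sentence
from .lexicons import _data_path, _read_tsv

__all__ = [
    "HeadingLexicon",
    "CorpusStats",
    "load_headings",
    "default_headings",
    "detect_headings",
    "autolabel",
    "strip_headings",
    "build_corpus",
]


@dataclass
class HeadingLexicon:
    """Uppercase-normalized heading strings per element, plus known
    non-PICO headings (stripped but never used for labeling)."""

    by_element: dict[Element, frozenset[str]]
    other: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        sets = list(self.by_element.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"heading sets overlap: {sorted(overlap)}")

    def all_strippable(self) -> frozenset[str]:
        out: set[str] = set(self.other)
        for s in self.by_element.values():
            out |= s
        return frozenset(out)


@dataclass
class CorpusStats:
    """Abstract and sentence counts of each element dataset."""

    abstracts: dict[Element, int] = field(default_factory=dict)
    sentences: dict[Element, int] = field(default_factory=dict)

    def row(self, elem: Element) -> tuple[int, int]:
        return self.abstracts.get(elem, 0), self.sentences.get(elem, 0)


def load_headings(path: str | Path) -> HeadingLexicon:
    """Load a heading lexicon from TSV ``element<TAB>heading``.

    Element codes P/I/C/O assign labeling headings (C folds into I); the
    code OTHER registers headings that are stripped but never label.
    """
    by_elem: dict[Element, set[str]] = {e: set() for e in Element}
    other: set[str] = set()
    for elem_s, heading in _read_tsv(path, 2):
        code = elem_s.strip().upper()
        h = " ".join(heading.upper().split())
        if code == "OTHER":
            other.add(h)
        elif code == "C":
            by_elem[Element.I].add(h)
        else:
            by_elem[Element(code)].add(h)
    return HeadingLexicon({e: frozenset(s) for e, s in by_elem.items()}, frozenset(other))


def default_headings() -> HeadingLexicon:
    return load_headings(_data_path("headings.tsv"))


# ---------------------------------------------------------------------------

# Optional list markers a heading may sit behind ("1. PATIENTS: ...").
_LIST_MARKER = re.compile(r"^(?:[-–•*]|\(?\d{1,2}[.)])\s*")


def _match_heading(text: str, headings: Iterable[str]) -> str | None:
    """Return the longest heading that prefixes ``text`` (case-insensitive,
    followed by a colon), or None."""
    stripped = _LIST_MARKER.sub("", text.lstrip())
    upper = " ".join(stripped.upper().split())
    best = None
    for h in headings:
        if upper.startswith(h) and re.match(r"\s*:", upper[len(h):]):
            if best is None or len(h) > len(best):
                best = h
    return best


def _strip_prefix(text: str, heading: str) -> str:
    """Remove a matched heading (plus colon) from the front of ``text``."""
    stripped = _LIST_MARKER.sub("", text.lstrip())
    pattern = r"\s+".join(re.escape(w) for w in heading.split())
    m = re.match(pattern + r"\s*:\s*", stripped, flags=re.IGNORECASE)
    assert m is not None, (text, heading)
    return stripped[m.end():].strip()


def detect_headings(
    abstract: Abstract, lexicon: HeadingLexicon
) -> list[tuple[int, Element]]:
    """Find sentences opening with a distinctive PICO heading.

    A sentence matches when it begins (after optional list markers) with a
    lexicon heading followed by a colon; multi-word headings win over their
    prefixes.  Non-PICO headings such as METHODS or CONCLUSION never match.
    """
    out: list[tuple[int, Element]] = []
    for sent in abstract.sentences:
        for elem, headings in lexicon.by_element.items():
            if _match_heading(sent.text, headings) is not None:
                out.append((sent.index, elem))
                break
    return out


def autolabel(
    abstract: Abstract, lexicon: HeadingLexicon
) -> LabeledAbstract | None:
    """Distant-supervision labeling of one structured abstract.

    For each detected PICO heading the gold sentence is the first sentence
    carrying that element's content: the heading sentence itself when
    heading and content share a sentence, otherwise the next sentence.
    Only the first occurrence of each element counts, and exactly one
    sentence is labeled per element.  Abstracts with no PICO heading return
    None and are excluded from the corpus; an abstract may carry labels for
    a strict subset of {P, I, O}.
    """
    gold: dict[Element, int] = {}
    for idx, elem in detect_headings(abstract, lexicon):
        if elem in gold:
            continue  # first occurrence wins
        text = abstract.sentences[idx].text
        heading = _match_heading(text, lexicon.by_element[elem])
        content = _strip_prefix(text, heading)
        if content:
            gold[elem] = idx
        elif idx + 1 < len(abstract):
            gold[elem] = idx + 1
    if not gold:
        return None
    return LabeledAbstract(abstract, gold)


def strip_headings(
    labeled: LabeledAbstract, lexicon: HeadingLexicon
) -> LabeledAbstract:
    """Remove every heading prefix, converting the abstract to unstructured
    form.

    PICO and non-PICO headings are deleted alike; sentences left empty
    (heading-only lines) are dropped and gold indices remapped.  Idempotent:
    after stripping, no lexicon heading remains as a sentence prefix.
    """
    strippable = lexicon.all_strippable()
    new_texts: list[str | None] = []
    for sent in labeled.abstract.sentences:
        text = sent.text
        while True:
            h = _match_heading(text, strippable)
            if h is None:
                break
            text = _strip_prefix(text, h)
        new_texts.append(text if text else None)
    index_map: dict[int, int] = {}
    sentences: list[Sentence] = []
    for old_idx, text in enumerate(new_texts):
        if text is None:
            continue
        index_map[old_idx] = len(sentences)
        sentences.append(Sentence(len(sentences), text))
    gold: dict[Element, int] = {}
    for elem, old_idx in labeled.gold.items():
        if old_idx in index_map:
            gold[elem] = index_map[old_idx]
        elif old_idx + 1 in index_map:  # gold sentence vanished; fall forward
            gold[elem] = index_map[old_idx + 1]
    ab = labeled.abstract
    return LabeledAbstract(Abstract(ab.pmid, ab.title, sentences, None), gold)


def build_corpus(
    abstracts: Sequence[Abstract], lexicon: HeadingLexicon
) -> tuple[dict[Element, list[LabeledAbstract]], CorpusStats]:
    """Construct the three per-element datasets.

    Each abstract with at least one PICO heading is auto-labeled, stripped
    of all headings, and placed into the dataset of every element it has a
    gold sentence for.  Statistics count the abstracts and all their
    (post-stripping) sentences per dataset.
    """
    datasets: dict[Element, list[LabeledAbstract]] = {e: [] for e in Element}
    stats = CorpusStats({e: 0 for e in Element}, {e: 0 for e in Element})
    for ab in abstracts:
        la = autolabel(ab, lexicon)
        if la is None:
            continue
        stripped = strip_headings(la, lexicon)
        if not stripped.abstract.sentences:
            continue
        for elem in stripped.gold:
            datasets[elem].append(stripped)
            stats.abstracts[elem] += 1
            stats.sentences[elem] += len(stripped.abstract)
    return datasets, stats
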