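"""Token canonicalization and the three knowledge resources.

Three lexical resources drive the knowledge-based features:

* cue-words and cue-verbs, hand-curated triggers associated with one PICO
  element (e.g. "placebo" -> I, "recruit" -> P);
* three semantic-type term lists derived from MeSH/UMLS semantic groups —
  Living Beings, Disorders, and Chemicals & Drugs.

All resources are stored in canonical form: lowercased, number words
converted to digit strings, and suffix-stemmed, so that surface variation
("randomized" / "randomize" / "randomising") collapses before matching.

The shipped TSV files under ``picosense/data`` are small seed lists — the
printed cue examples plus a demonstration slice of each semantic group —
and are meant to be extended by users holding a MeSH/UMLS release.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .abstract_model import Element

__all__ = [
    "canonicalize",
    "tokenize",
    "canonical_tokens",
    "CueLexicon",
    "SemanticLexicon",
    "load_cues",
    "load_semantic",
    "count_matches",
    "default_cues",
    "default_semantic",
]

_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?|[A-Za-z\d]+(?:[-'][A-Za-z\d]+)*|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Split text into word, number, and punctuation tokens."""
    return _TOKEN_RE.findall(text)


# --- number-word conversion -------------------------------------------------

_UNITS = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}
_SCALES = {"hundred": 100, "thousand": 1000}


def _number_word_value(token: str) -> int | None:
    """Value of a cardinal number word, hyphenated compounds included.

    Handles "twenty" -> 20, "twenty-five" -> 25, "three-hundred-twenty-five"
    -> 325, up to 999,999.  Returns None for anything else (ordinals stay
    words).
    """
    parts = token.lower().split("-")
    total = 0
    current = 0
    for p in parts:
        if p in _UNITS:
            current += _UNITS[p]
        elif p in _TENS:
            current += _TENS[p]
        elif p in _SCALES:
            if p == "hundred":
                current = (current or 1) * 100
            else:  # thousand
                total += (current or 1) * 1000
                current = 0
        elif p == "and" and len(parts) > 1:
            continue
        else:
            return None
    value = total + current
    return value if value <= 999_999 else None


# --- light suffix stemmer ---------------------------------------------------


def _stem_once(w: str) -> str:
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "i"
    if len(w) > 4 and w.endswith("ied"):
        return w[:-3] + "i"
    if len(w) > 4 and w.endswith("sses"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if len(w) > 4 and w.endswith("ing"):
        return w[:-3]
    if len(w) > 3 and w.endswith("ed"):
        return w[:-2]
    if len(w) > 3 and w.endswith("es"):
        return w[:-2]
    if len(w) > 3 and w.endswith("s"):
        return w[:-1]
    if len(w) > 3 and w.endswith("e"):
        return w[:-1]
    if len(w) > 3 and w.endswith("y"):
        return w[:-1] + "i"
    return w


def _stem(w: str) -> str:
    # iterate to a fixpoint so canonicalize is idempotent by construction
    for _ in range(6):
        nxt = _stem_once(w)
        if nxt == w:
            return w
        w = nxt
    return w


def canonicalize(token: str) -> str:
    """Map one token to its canonical form.

    Lowercase, convert cardinal number words to digit strings ("twenty" ->
    "20"), and suffix-stem alphabetic tokens so inflectional variants
    collapse ("randomized" and "randomize" share one form).  Deterministic
    and idempotent.
    """
    t = token.lower()
    value = _number_word_value(t)
    if value is not None:
        return str(value)
    if re.fullmatch(r"[a-z]+(?:[-'][a-z]+)*", t):
        return _stem(t)
    return t


def canonical_tokens(text: str) -> list[str]:
    return [canonicalize(t) for t in tokenize(text)]


# --- lexicon containers -----------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("picosense").joinpath("data", name)))


@dataclass
class CueLexicon:
    """Per-element cue-word and cue-verb sets, canonical forms."""

    words: dict[Element, frozenset[str]] = field(default_factory=dict)
    verbs: dict[Element, frozenset[str]] = field(default_factory=dict)

    def words_for(self, elem: Element) -> frozenset[str]:
        return self.words.get(elem, frozenset())

    def verbs_for(self, elem: Element) -> frozenset[str]:
        return self.verbs.get(elem, frozenset())


@dataclass
class SemanticLexicon:
    """The three MeSH-derived term lists, keyed 1..3.

    Terms are stored as tuples of canonical tokens so multi-word entries
    ("acute febrile illness") can be matched greedily; ``types`` carries the
    UMLS semantic-type identifiers of each list as metadata.
    """

    terms: dict[int, frozenset[tuple[str, ...]]] = field(default_factory=dict)
    types: dict[int, frozenset[str]] = field(default_factory=dict)

    def list_terms(self, list_id: int) -> frozenset[tuple[str, ...]]:
        return self.terms.get(list_id, frozenset())


def _read_tsv(path: str | Path, n_cols: int) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} tab-separated fields, "
                    f"got {len(cols)}"
                )
            rows.append(cols)
    return rows


def load_cues(path: str | Path) -> CueLexicon:
    """Load a cue lexicon from TSV lines ``element<TAB>{word|verb}<TAB>term``.

    Entries are canonicalized on load; duplicates collapse.  The C element
    code is accepted and folded into I.
    """
    words: dict[Element, set[str]] = {e: set() for e in Element}
    verbs: dict[Element, set[str]] = {e: set() for e in Element}
    for elem_s, kind, term in _read_tsv(path, 3):
        elem = Element.I if elem_s.strip().upper() == "C" else Element(elem_s.strip().upper())
        canon = " ".join(canonical_tokens(term)).strip()
        if not canon:
            continue
        if kind.strip().lower() == "word":
            words[elem].add(canon)
        elif kind.strip().lower() == "verb":
            verbs[elem].add(canon)
        else:
            raise ValueError(f"{path}: unknown cue kind {kind!r}")
    return CueLexicon(
        {e: frozenset(s) for e, s in words.items()},
        {e: frozenset(s) for e, s in verbs.items()},
    )


def load_semantic(paths: Sequence[str | Path] | str | Path) -> SemanticLexicon:
    """Load semantic term lists from TSV ``list_id<TAB>type_code<TAB>term``."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    terms: dict[int, set[tuple[str, ...]]] = {}
    types: dict[int, set[str]] = {}
    for path in paths:
        for list_s, type_code, term in _read_tsv(path, 3):
            list_id = int(list_s)
            canon = tuple(t for t in canonical_tokens(term) if t.isalnum() or "-" in t)
            if not canon:
                continue
            terms.setdefault(list_id, set()).add(canon)
            if type_code.strip():
                types.setdefault(list_id, set()).add(type_code.strip())
    return SemanticLexicon(
        {k: frozenset(v) for k, v in terms.items()},
        {k: frozenset(v) for k, v in types.items()},
    )


def default_cues() -> CueLexicon:
    return load_cues(_data_path("cues.tsv"))


def default_semantic() -> SemanticLexicon:
    return load_semantic(_data_path("semantic_terms.tsv"))


# --- term matching ----------------------------------------------------------


def count_matches(tokens: Sequence[str], terms: Iterable[tuple[str, ...]]) -> int:
    """Count term occurrences by greedy longest-match, left to right.

    ``tokens`` must already be canonical.  Each token is consumed by at most
    one match, so overlapping candidates resolve in favour of the longest
    term starting earliest.
    """
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for term in terms:
        if term:
            by_first.setdefault(term[0], []).append(term)
    for cands in by_first.values():
        cands.sort(key=len, reverse=True)
    count = 0
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for term in by_first.get(tokens[i], ()):
            k = len(term)
            if i + k <= n and tuple(tokens[i : i + k]) == term:
                count += 1
                i += k
                matched = True
                break
        if not matched:
            i += 1
    return count
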