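"""Core data model for abstract corpora: sentences, abstracts, gold labels, and I/O.

The unit of classification throughout the package is the sentence.  An
:class:`Abstract` is an ordered list of sentences plus a PMID and title;
a :class:`LabeledAbstract` adds a gold map assigning at most one sentence
index to each PICO element (P, I, O — the Comparison element is merged
into I because intervention and comparison arms are rarely separable).

Supported corpus formats:

``jsonl``
    The internal canonical format: one JSON object per line with keys
    ``pmid``, ``title``, ``sentences`` and optionally ``headings`` and
    ``gold``.  Round-trips losslessly.
``medline``
    MEDLINE flat files (``PMID``/``TI``/``AB`` tags) via ``Bio.Medline``;
    the abstract body is segmented on read.
``plain``
    Blank-line-separated blocks; the first line of a block is the title,
    the rest the abstract body.  PMIDs are assigned ordinally.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Medline

__all__ = [
    "Element",
    "Sentence",
    "Abstract",
    "LabeledAbstract",
    "segment",
    "read_abstracts",
    "read_labeled",
    "write_abstracts",
]


class Element(str, Enum):
    """A PICO element label. Comparison is subsumed by I."""

    P = "P"
    I = "I"
    O = "O"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Sentence:
    """One sentence of an abstract.

    ``index`` is the 0-based position within the abstract; ``text`` is the
    raw character string.  Canonical-form tokens are computed on demand by
    :mod:`picosense.lexicons` rather than stored, so a ``Sentence`` is a
    plain value object.
    """

    index: int
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"sentence {self.index} is empty")


@dataclass
class Abstract:
    pmid: str
    title: str
    sentences: list[Sentence]
    headings: list[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sentences):
            if s.index != i:
                raise ValueError(
                    f"abstract {self.pmid}: sentence index {s.index} at position {i}"
                )
        if self.headings:
            n = len(self.sentences)
            for idx, _ in self.headings:
                if not 0 <= idx < n:
                    raise ValueError(f"abstract {self.pmid}: heading index {idx} out of range")

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class LabeledAbstract:
    """An abstract plus a gold map: at most one sentence index per element."""

    abstract: Abstract
    gold: dict[Element, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.abstract)
        for elem, idx in self.gold.items():
            if not 0 <= idx < n:
                raise ValueError(
                    f"abstract {self.abstract.pmid}: gold index {idx} for {elem} out of range"
                )

    @property
    def pmid(self) -> str:
        return self.abstract.pmid


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

# Abbreviations after which a period does not end a sentence.  Extended for
# clinical prose; compared lowercase against the token preceding the period
# (internal dots kept, so "e.g." matches as "e.g").
_ABBREVIATIONS = frozenset(
    {
        "vs", "dr", "mr", "mrs", "ms", "prof", "fig", "figs", "e.g", "i.e",
        "al", "no", "st", "ca", "cf", "approx", "resp", "i.p", "i.v", "s.c",
        "p.o", "b.i.d", "t.i.d", "q.d", "inc", "ltd", "jr", "sr", "ref",
    }
)

# A terminator followed by whitespace and a plausible sentence opener.
_BOUNDARY = re.compile(r"[.!?]+(?=\s+[\"'(\[]?[A-Z0-9])")

# An embedded section heading — an uppercase run (optionally multi-word)
# followed by a colon — starts a new sentence even without a terminator.
_HEADING_START = re.compile(r"(?<=[a-z0-9,;%)\]])\s+(?=[A-Z][A-Z &/\-]{2,}[A-Z]\s*:)")


def _token_before(text: str, pos: int) -> str:
    m = re.search(r"([A-Za-z][\w.]*)$", text[:pos])
    return m.group(1).lower() if m else ""


def segment(text: str) -> list[Sentence]:
    """Split plain prose into sentences.

    Deterministic and total: empty input yields an empty list, and joining
    the sentence texts recovers the input up to whitespace.  Periods after
    clinical abbreviations ("vs.", "e.g.", "i.p.") and single initials do
    not split; an embedded ALL-CAPS heading followed by a colon always
    starts a new sentence.
    """
    text = unicodedata.normalize("NFC", text)
    if not text.strip():
        return []
    cuts: set[int] = set()
    for m in _BOUNDARY.finditer(text):
        tok = _token_before(text, m.start())
        bare = tok.rstrip(".")
        if bare in _ABBREVIATIONS:
            continue
        if tok and len(bare) == 1 and tok[0].isupper():
            continue  # single initial, e.g. "J."
        cuts.add(m.end())
    for m in _HEADING_START.finditer(text):
        cuts.add(m.start())
    pieces: list[str] = []
    start = 0
    for cut in sorted(cuts):
        piece = text[start:cut].strip()
        if piece:
            pieces.append(piece)
        start = cut
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    return [Sentence(i, p) for i, p in enumerate(pieces)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _labeled_to_record(la: LabeledAbstract) -> dict:
    ab = la.abstract
    rec: dict = {
        "pmid": ab.pmid,
        "title": ab.title,
        "sentences": [s.text for s in ab.sentences],
    }
    if ab.headings:
        rec["headings"] = [[i, h] for i, h in ab.headings]
    if la.gold:
        rec["gold"] = {e.value: i for e, i in la.gold.items()}
    return rec


def _record_to_labeled(rec: dict, ordinal: int) -> LabeledAbstract:
    try:
        sentences = [Sentence(i, t) for i, t in enumerate(rec["sentences"])]
        headings = [(int(i), str(h)) for i, h in rec.get("headings", [])] or None
        ab = Abstract(str(rec["pmid"]), str(rec.get("title", "")), sentences, headings)
        gold = {Element(k): int(v) for k, v in rec.get("gold", {}).items()}
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed jsonl record {ordinal}: {exc}") from exc
    return LabeledAbstract(ab, gold)


def read_labeled(path: str | Path) -> list[LabeledAbstract]:
    """Read a JSONL corpus, preserving gold labels."""
    out: list[LabeledAbstract] = []
    with open(path, encoding="utf-8") as fh:
        for ordinal, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed jsonl record {ordinal}: {exc}") from exc
            out.append(_record_to_labeled(rec, ordinal))
    return out


def read_abstracts(path: str | Path, format: str = "jsonl") -> list[Abstract]:
    """Read a corpus of abstracts. ``format`` is one of jsonl/medline/plain.

    Gold labels in a JSONL file are dropped; use :func:`read_labeled` to
    keep them.  MEDLINE and plain text bodies are sentence-segmented.
    """
    if format == "jsonl":
        return [la.abstract for la in read_labeled(path)]
    if format == "medline":
        out = []
        with open(path, encoding="utf-8") as fh:
            for ordinal, rec in enumerate(Medline.parse(fh)):
                pmid = rec.get("PMID")
                body = rec.get("AB", "")
                if not pmid:
                    raise ValueError(f"malformed medline record {ordinal}: missing PMID")
                if not body.strip():
                    raise ValueError(
                        f"malformed medline record {ordinal} (PMID {pmid}): missing AB"
                    )
                out.append(Abstract(pmid, rec.get("TI", ""), segment(body)))
        return out
    if format == "plain":
        text = Path(path).read_text(encoding="utf-8")
        out = []
        for ordinal, block in enumerate(b for b in re.split(r"\n\s*\n", text) if b.strip()):
            lines = block.strip().split("\n")
            title = lines[0].strip()
            body = " ".join(ln.strip() for ln in lines[1:])
            if not body:
                raise ValueError(f"malformed plain record {ordinal}: title without body")
            out.append(Abstract(str(ordinal + 1), title, segment(body)))
        return out
    raise ValueError(f"unknown format: {format!r}")


def write_abstracts(
    path: str | Path, corpus: Sequence[LabeledAbstract | Abstract]
) -> None:
    """Write a corpus as JSONL, one abstract per line.

    Accepts labeled or bare abstracts; ``read_labeled`` inverts it and the
    write-read-write cycle is byte-identical.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for item in corpus:
            la = item if isinstance(item, LabeledAbstract) else LabeledAbstract(item)
            fh.write(json.dumps(_labeled_to_record(la), ensure_ascii=False, sort_keys=True))
            fh.write("\n")
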