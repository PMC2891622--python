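"""Seeded generator of synthetic structured abstracts.

Real clinical-trial corpora cannot be bundled, so this module fabricates
abstracts that reproduce the structural properties the pipeline relies
on: ordered sections with uppercase headings (objective and methods
filler, then Population, Intervention/Comparison and Outcome sections,
then results/conclusion filler), element-specific cue vocabulary in the
gold sentences, large enrollment counts and "(n = ...)" patterns in
Population sentences, and a controllable amount of label noise.

The text itself is deliberately non-linguistic — filler sentences are
pseudo-word strings — which is exactly what the shallow feature scheme
needs: position, numbers, punctuation and lexicon hits are realistic;
grammar is not.  See docs/methods.md for what that implies about
transferring results to real abstracts.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``GenConfig.seed``, so generation is byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .abstract_model import Abstract, Element, Sentence

__all__ = ["GenConfig", "generate"]


@dataclass(frozen=True)
class GenConfig:
    """Knobs of the synthetic corpus.

    ``cue_signal`` is the probability that each cue slot of a gold
    sentence draws from its element's cue vocabulary instead of filler;
    at 0 gold sentences are lexically indistinguishable from filler and
    only position carries information.  ``noise`` is the probability that
    a PICO heading is attached to an uninformative sentence while the
    truly informative sentence lands next to it unheaded — the failure
    mode of distant supervision.
    """

    n_abstracts: int = 1000
    sentences_range: tuple[int, int] = (8, 18)  # mean ~13, matching
    # the ~13.4 sentences/abstract density of heading-selected RCT corpora
    include_p: float = 0.95
    include_i: float = 0.85
    include_o: float = 0.70
    cue_signal: float = 0.9
    position_priors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"P": (0.25, 0.08), "I": (0.45, 0.08), "O": (0.65, 0.08)}
    )
    numeric_rate: float = 0.9  # large enrollment count in gold-P sentences
    n_pattern_rate: float = 0.4  # "(n = ...)" in gold-P sentences
    noise: float = 0.0
    vocab_size: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("include_p", "include_i", "include_o", "cue_signal",
                     "numeric_rate", "n_pattern_rate", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_abstracts < 1:
            raise ValueError("n_abstracts must be >= 1")
        lo, hi = self.sentences_range
        if not 3 <= lo <= hi:
            raise ValueError("sentences_range must satisfy 3 <= lo <= hi")


# Surface forms whose canonical stems hit the shipped cue lexicon; the
# inflectional variety exercises the stemmer on purpose.
_CUE_SURFACE: dict[Element, list[str]] = {
    Element.P: [
        "population", "populations", "group", "groups", "patients",
        "participants", "adults", "women", "conducted", "recruited",
        "enrolled", "screened",
    ],
    Element.I: [
        "placebo", "treatment", "treatments", "drug", "dose", "randomized",
        "randomised", "prescribed", "administered", "allocated",
    ],
    Element.O: [
        "mortality", "outcome", "outcomes", "rate", "rates", "score",
        "scores", "assessed", "recorded", "measured", "evaluated", "endpoint",
    ],
}

# Semantic-list terms planted alongside cues (list 1 / 2 / 3 flavours).
_SEM_SURFACE: dict[Element, list[str]] = {
    Element.P: ["patients", "children", "adults", "pregnant women", "elderly", "smokers"],
    Element.I: ["aspirin", "metformin", "growth hormone", "insulin", "statin", "vaccine"],
    Element.O: ["pain", "stroke", "fracture", "nausea", "depression", "fever"],
}

_HEADINGS: dict[Element, list[str]] = {
    Element.P: ["POPULATION", "PARTICIPANTS", "PATIENTS", "SUBJECTS", "SAMPLE"],
    Element.I: ["INTERVENTION", "INTERVENTIONS", "COMPARISON"],
    Element.O: ["OUTCOME", "OUTCOMES", "MAIN OUTCOME MEASURES", "PRIMARY OUTCOME"],
}

_FILLER_HEADINGS = ["OBJECTIVE", "METHODS", "RESULTS", "CONCLUSION"]

_SYLLABLES = ["ba", "do", "ke", "lu", "mi", "no", "pa", "ri", "sa", "tu", "ve", "zo"]


def _build_vocab(size: int) -> list[str]:
    words = []
    for n_syll in (2, 3):
        for combo in itertools.product(_SYLLABLES, repeat=n_syll):
            words.append("".join(combo))
            if len(words) >= size:
                return words
    return words


def _filler_sentence(
    rng: np.random.Generator, vocab: list[str], distractors: list[str]
) -> str:
    n_words = int(rng.integers(6, 14))
    words = list(rng.choice(vocab, size=n_words))
    for d in distractors:
        words[int(rng.integers(0, n_words))] = d
    # real abstracts scatter numbers outside the population sentence too
    if rng.random() < 0.3:
        words.append(str(int(rng.integers(1, 5000))))
    return " ".join(words).capitalize() + "."


def _gold_content(
    rng: np.random.Generator, elem: Element, cfg: GenConfig, vocab: list[str]
) -> str:
    words: list[str] = []
    cues = _CUE_SURFACE[elem]
    sems = _SEM_SURFACE[elem]
    if elem is Element.P and rng.random() < cfg.numeric_rate:
        words.append(str(int(rng.integers(20, 5000))))
    for _ in range(3):  # three cue slots
        if rng.random() < cfg.cue_signal:
            words.append(str(rng.choice(cues)))
        else:
            words.append(str(rng.choice(vocab)))
    if rng.random() < cfg.cue_signal:
        words.append(str(rng.choice(sems)))
    words.extend(rng.choice(vocab, size=int(rng.integers(2, 6))))
    if elem is Element.O and rng.random() < 0.5:
        words.append(str(int(rng.integers(1, 10))))
    rng.shuffle(words)
    text = " ".join(words)
    if elem is Element.P and rng.random() < cfg.n_pattern_rate:
        text += f" (n = {int(rng.integers(20, 5000))})"
    return text + "."


def generate(config: GenConfig) -> tuple[list[Abstract], dict[str, dict[Element, int]]]:
    """Generate structured abstracts plus the hidden gold map.

    Returns ``(abstracts, gold)`` where ``gold[pmid][element]`` is the
    index of the truly informative sentence.  With ``noise=0`` the hidden
    gold coincides with what heading-based auto-labeling recovers; with
    noise > 0 a fraction of headings sit on uninformative sentences.
    Deterministic: the same config (seed included) regenerates the corpus
    byte-identically.
    """
    rng = np.random.default_rng(config.seed)
    vocab = _build_vocab(config.vocab_size)
    abstracts: list[Abstract] = []
    gold_map: dict[str, dict[Element, int]] = {}

    include_prob = {
        Element.P: config.include_p,
        Element.I: config.include_i,
        Element.O: config.include_o,
    }

    for i in range(config.n_abstracts):
        pmid = str(90000000 + i)
        lo, hi = config.sentences_range
        n_sent = int(rng.integers(lo, hi + 1))
        included = [e for e in Element if rng.random() < include_prob[e]]

        # draw target slots from the position priors, then sort so the
        # canonical P -> I -> O section order always holds
        slots: dict[Element, int] = {}
        if included:
            draws = []
            for e in included:
                mu, sd = config.position_priors[e.value]
                draws.append(float(np.clip(rng.normal(mu, sd), 0.08, 0.92)))
            draws.sort()
            used: set[int] = set()
            for e, rel in zip(included, draws):  # Element order == P, I, O
                idx = int(round(rel * (n_sent - 1)))
                while idx in used and idx < n_sent - 1:
                    idx += 1
                while idx in used:
                    idx -= 1
                used.add(idx)
                slots[e] = idx

        sentences: list[str] = []
        headings: list[tuple[int, str]] = []
        gold: dict[Element, int] = {}
        noisy: set[Element] = {
            e for e in slots if rng.random() < config.noise and slots[e] + 1 < n_sent
        }

        for idx in range(n_sent):
            elem = next((e for e, s in slots.items() if s == idx), None)
            if elem is not None:
                heading = str(rng.choice(_HEADINGS[elem]))
                if elem in noisy:
                    # heading lands on filler; real content follows unheaded
                    body = _filler_sentence(rng, vocab, [])
                    sentences.append(f"{heading}: {body}")
                    headings.append((idx, heading))
                else:
                    content = _gold_content(rng, elem, config, vocab)
                    sentences.append(f"{heading}: {content}")
                    headings.append((idx, heading))
                    gold[elem] = idx
            elif any(e in noisy and slots[e] + 1 == idx for e in noisy):
                elem_n = next(e for e in noisy if slots[e] + 1 == idx)
                content = _gold_content(rng, elem_n, config, vocab)
                sentences.append(content[0].upper() + content[1:])
                gold[elem_n] = idx
            else:
                # terms of every element leak into other sentences, as drug
                # and population vocabulary does in real abstracts
                distractors: list[str] = []
                if rng.random() < 0.30:
                    for _ in range(int(rng.integers(1, 3))):
                        pool_elem = Element(rng.choice(list(Element)))
                        distractors.append(str(rng.choice(_CUE_SURFACE[pool_elem])))
                body = _filler_sentence(rng, vocab, distractors)
                if idx == 0:
                    sentences.append(f"OBJECTIVE: {body}")
                    headings.append((0, "OBJECTIVE"))
                elif idx == n_sent - 1:
                    sentences.append(f"CONCLUSION: {body}")
                    headings.append((idx, "CONCLUSION"))
                elif rng.random() < 0.25:
                    h = str(rng.choice(_FILLER_HEADINGS[1:3]))
                    sentences.append(f"{h}: {body}")
                    headings.append((idx, h))
                else:
                    sentences.append(body)

        # title shares tokens with the gold sentences so title-overlap fires
        title_words = [str(w) for w in rng.choice(vocab, size=3)]
        for e in gold:
            toks = [
                w for w in sentences[gold[e]].split() if w.isalpha() and w.islower()
            ]
            if toks and rng.random() < 0.7:
                title_words.append(str(rng.choice(toks)))
        rng.shuffle(title_words)
        title = " ".join(title_words).capitalize()

        ab = Abstract(
            pmid,
            title,
            [Sentence(j, t) for j, t in enumerate(sentences)],
            headings or None,
        )
        abstracts.append(ab)
        gold_map[pmid] = gold

    return abstracts, gold_map
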