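"""Sentence splitting, co-occurrence filtering, and corpus-unit expansion.

These are the corpus-construction steps between raw abstracts and the
annotation sheet: split an abstract into sentences, keep the sentences where
at least one plant and at least one chemical mention co-occur, and expand
each such sentence into one candidate corpus unit per (plant, chemical)
mention pair.

The sentence splitter is pluggable; the default is rule-based (a ``.``,
``!`` or ``?`` followed by whitespace and an uppercase letter or digit ends
a sentence, with a guard list of common abbreviations and single-initial
tokens).
"""

from __future__ import annotations

import random
import re
from itertools import product
from typing import Callable, Iterable, Sequence

from .model import CorpusUnit, EntityClass, Label, SentenceRecord

__all__ = [
    "split_sentences",
    "find_cooccurrence",
    "expand_units",
    "sample_units",
    "DEFAULT_ABBREVIATIONS",
]

Splitter = Callable[[str], list[tuple[int, str]]]

#: Tokens (sans the trailing period) that do not end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "cf", "al", "et al", "fig", "figs", "vs", "sp", "spp",
        "var", "cv", "approx", "ca", "no", "dr", "prof", "inc", "ltd",
    }
)

_BOUNDARY = re.compile(r"[.!?](?=\s+[A-Z0-9])")
_LAST_WORD = re.compile(r"(\S+)\s*$")


def _guarded(text: str, period_at: int, abbreviations: frozenset[str]) -> bool:
    if text[period_at] != ".":
        return False
    m = _LAST_WORD.search(text, 0, period_at)
    if not m:
        return False
    word = m.group(1).rstrip(".")
    if re.fullmatch(r"[A-Z]", word):  # single initial, "A. thaliana" style
        return True
    return word.lower() in abbreviations


def split_sentences(
    abstract_text: str,
    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
) -> list[tuple[int, str]]:
    """Split an abstract into ``(doc_offset, sentence_text)`` records.

    The returned spans are ordered, disjoint, and jointly cover every
    non-whitespace character of the input.
    """
    cut_points = [
        m.start() + 1
        for m in _BOUNDARY.finditer(abstract_text)
        if not _guarded(abstract_text, m.start(), abbreviations)
    ]
    spans = []
    start = 0
    for cut in cut_points + [len(abstract_text)]:
        chunk = abstract_text[start:cut]
        lead = len(chunk) - len(chunk.lstrip())
        trimmed = chunk.strip()
        if trimmed:
            spans.append((start + lead, trimmed))
        start = cut
    return spans


def find_cooccurrence(sentences: Iterable[SentenceRecord]) -> list[SentenceRecord]:
    """Exactly the sentences with >= 1 plant and >= 1 chemical mention."""
    return [
        s
        for s in sentences
        if s.mentions_of(EntityClass.PLANT) and s.mentions_of(EntityClass.CHEMICAL)
    ]


def expand_units(sentence: SentenceRecord) -> list[CorpusUnit]:
    """One UNLABELED candidate unit per (plant, chemical) mention pair.

    Ordered by plant span, then chemical span; the count is always
    ``#plants * #chemicals``.
    """
    plants = sorted(sentence.mentions_of(EntityClass.PLANT), key=lambda m: m.span)
    chems = sorted(sentence.mentions_of(EntityClass.CHEMICAL), key=lambda m: m.span)
    return [
        CorpusUnit(sentence=sentence, plant=p, chemical=c, label=Label.UNLABELED)
        for p, c in product(plants, chems)
    ]


def sample_units(
    units: Sequence[CorpusUnit], k: int, seed: int
) -> list[CorpusUnit]:
    """Seeded random sample of candidate units (for manual curation)."""
    rng = random.Random(seed)
    return rng.sample(list(units), k)
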