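"""Dictionary-based exact-match named entity recognition.

The matcher is case-insensitive, token-boundary anchored (a term never
matches inside a longer alphanumeric run, but hyphens count as boundaries,
so "tobacco" is found inside "tobacco-specific"), and selects matches
left-to-right preferring the longest term at each position, without
overlaps — the classic dictionary-chunker policy.

The chemical recognizer slot is pluggable: any callable mapping sentence
text to a list of :class:`~plantchem.model.EntityMention` can stand in for
the default dictionary matcher (e.g. an adapter around a statistical
chemical NER system).
"""

from __future__ import annotations

import logging
from typing import Callable, Protocol

from .lexicons import NameLexicon
from .model import AbstractDoc, EntityClass, EntityMention

logger = logging.getLogger(__name__)

__all__ = ["match_mentions", "annotate_abstract", "Recognizer", "dictionary_recognizer"]


class Recognizer(Protocol):
    """Contract for a pluggable mention recognizer."""

    def __call__(self, sentence_text: str) -> list[EntityMention]: ...


def _is_boundary(text: str, i: int, j: int) -> bool:
    before_ok = i == 0 or not text[i - 1].isalnum()
    after_ok = j == len(text) or not text[j].isalnum()
    return before_ok and after_ok


def match_mentions(sentence_text: str, lexicon: NameLexicon) -> list[EntityMention]:
    """All longest-match, non-overlapping lexicon hits in a sentence."""
    lowered = sentence_text.lower()
    candidates: dict[tuple[int, int], set[tuple[str, str]]] = {}
    for term, ids in lexicon.entries.items():
        needle = term.lower()
        start = 0
        while True:
            i = lowered.find(needle, start)
            if i < 0:
                break
            j = i + len(needle)
            if _is_boundary(sentence_text, i, j):
                candidates.setdefault((i, j), set()).update(ids)
            start = i + 1
    selected: list[EntityMention] = []
    last_end = -1
    for (i, j) in sorted(candidates, key=lambda span: (span[0], -span[1])):
        if i >= last_end:
            selected.append(
                EntityMention(
                    entity_class=lexicon.entity_class,
                    start=i,
                    end=j,
                    text=sentence_text[i:j],
                    ids=tuple(sorted(candidates[(i, j)])),
                )
            )
            last_end = j
    return selected


def dictionary_recognizer(
    lexicon: NameLexicon,
) -> Callable[[str], list[EntityMention]]:
    """Wrap a name lexicon as a :class:`Recognizer`."""

    def recognize(sentence_text: str) -> list[EntityMention]:
        return match_mentions(sentence_text, lexicon)

    return recognize


def _resolve_cross_class(
    plants: list[EntityMention], chemicals: list[EntityMention]
) -> list[EntityMention]:
    # Longer span wins across classes; equal spans go to the plant.  Same-class
    # overlaps were already resolved by the matcher's longest-match policy.
    ranked = sorted(
        plants + chemicals,
        key=lambda m: (
            -(m.end - m.start),
            0 if m.entity_class is EntityClass.PLANT else 1,
            m.start,
        ),
    )
    kept: list[EntityMention] = []
    for m in ranked:
        clash = any(
            k.entity_class is not m.entity_class
            and k.start < m.end
            and k.end > m.start
            for k in kept
        )
        if not clash:
            kept.append(m)
        else:
            logger.debug(
                "dropping %s mention %r overlapped by a longer/preferred mention",
                m.entity_class.value,
                m.text,
            )
    return sorted(kept, key=lambda m: (m.start, m.end))


def annotate_abstract(
    doc: AbstractDoc,
    plant_lexicon: NameLexicon,
    chem_recognizer: Recognizer,
) -> AbstractDoc:
    """Populate every sentence's mentions (plants via dictionary, chemicals
    via the supplied recognizer).

    A recognizer failure skips the affected sentence with a warning rather
    than aborting the abstract.
    """
    for sent in doc.sentences:
        try:
            plants = match_mentions(sent.text, plant_lexicon)
            chems = [
                m
                for m in chem_recognizer(sent.text)
                if m.entity_class is EntityClass.CHEMICAL
            ]
        except Exception:  # noqa: BLE001 - recognizer contract violation
            logger.warning(
                "recognizer failed on sentence at offset %d of %s; skipped",
                sent.doc_offset,
                doc.pmid,
                exc_info=True,
            )
            continue
        sent.mentions = _resolve_cross_class(plants, chems)
        sent.pmid = doc.pmid
    return doc
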