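"""Shared document data model.

The unit of annotation and evaluation throughout the package is the *corpus
unit*: one (plant mention, chemical mention) pair inside a single sentence,
labelled POS when the sentence states that the plant contains / yields the
chemical and NEG otherwise.  Abstracts are held as :class:`AbstractDoc`
(ordered sentences with character offsets into the abstract text); entity
mentions carry sentence-relative, 0-based half-open character spans plus
database identifiers.

Identifier namespaces are restricted by entity class, mirroring the
annotation guidelines: plants may carry Taxonomy or TCMID ids, chemicals
MeSH, CHEMBL or CAS ids; an empty id list stands for the literal "NA"
placeholder.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import IntegrityError, ValidationError

__all__ = [
    "Label",
    "EntityClass",
    "EntityMention",
    "SentenceRecord",
    "AbstractDoc",
    "CorpusUnit",
    "EvalResult",
    "PLANT_NAMESPACES",
    "CHEMICAL_NAMESPACES",
]

PLANT_NAMESPACES = frozenset({"Taxonomy", "TCMID"})
CHEMICAL_NAMESPACES = frozenset({"MeSH", "CHEMBL", "CAS"})


class Label(str, enum.Enum):
    POS = "POS"
    NEG = "NEG"
    UNLABELED = "UNLABELED"


class EntityClass(str, enum.Enum):
    PLANT = "plant"
    CHEMICAL = "chemical"


def allowed_namespaces(entity_class: EntityClass) -> frozenset[str]:
    if entity_class is EntityClass.PLANT:
        return PLANT_NAMESPACES
    return CHEMICAL_NAMESPACES


@dataclass(frozen=True)
class EntityMention:
    """A plant or chemical name with a sentence-relative character span.

    ``ids`` is a tuple of ``(namespace, value)`` pairs; an empty tuple is the
    "NA" placeholder of the annotation sheet.
    """

    entity_class: EntityClass
    start: int
    end: int
    text: str
    ids: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValidationError(
                f"mention span [{self.start}, {self.end}) is empty or negative"
            )
        allowed = allowed_namespaces(self.entity_class)
        for ns, _ in self.ids:
            if ns not in allowed:
                raise ValidationError(
                    f"namespace {ns!r} not allowed for {self.entity_class.value} "
                    f"mentions (allowed: {sorted(allowed)} or NA)"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def validate_against(self, sentence_text: str) -> None:
        if self.end > len(sentence_text) or sentence_text[self.start : self.end] != self.text:
            raise IntegrityError(
                f"mention text {self.text!r} does not match sentence substring "
                f"{sentence_text[self.start:self.end]!r} at "
                f"[{self.start}, {self.end})"
            )


@dataclass
class SentenceRecord:
    """One sentence of an abstract with its entity mentions.

    ``doc_offset`` is the 0-based character start of the sentence in the
    abstract text; ``pmid`` is carried for sheet export (empty when unknown).
    """

    doc_offset: int
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    pmid: str = ""

    def mentions_of(self, entity_class: EntityClass) -> list[EntityMention]:
        return [m for m in self.mentions if m.entity_class is entity_class]

    def validate(self) -> None:
        for m in self.mentions:
            m.validate_against(self.text)
        for cls in EntityClass:
            spans = sorted(m.span for m in self.mentions_of(cls))
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping {cls.value} mentions at {s1}-{e1} and {s2}"
                    )


@dataclass
class AbstractDoc:
    """A PubMed abstract: pmid, full text, and ordered sentence records."""

    pmid: str
    text: str
    sentences: list[SentenceRecord] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.pmid:
            raise ValidationError("pmid must be non-empty")
        prev_end = 0
        for sent in self.sentences:
            start, end = sent.doc_offset, sent.doc_offset + len(sent.text)
            if start < prev_end or end > len(self.text):
                raise ValidationError(
                    f"sentence span [{start}, {end}) out of order or outside "
                    f"document {self.pmid}"
                )
            if self.text[start:end] != sent.text:
                raise ValidationError(
                    f"sentence text mismatch at offset {start} in {self.pmid}"
                )
            sent.validate()
            prev_end = end


@dataclass(eq=False)
class CorpusUnit:
    """One (plant, chemical) pair in one sentence with its relation label.

    POS units must carry both a weak trigger (token sequence, as annotated)
    and a strong trigger (exactly one word); NEG units carry neither.
    ``provenance`` mirrors the annotation-sheet bookkeeping fields
    (``p_check``/``p_note``/``c_check``/``c_note`` and any extra keys such as
    model predictions).
    """

    sentence: SentenceRecord
    plant: EntityMention
    chemical: EntityMention
    label: Label = Label.UNLABELED
    weak_trigger: tuple[str, ...] | None = None
    strong_trigger: str | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plant.entity_class is not EntityClass.PLANT:
            raise ValidationError("plant slot must hold a PLANT mention")
        if self.chemical.entity_class is not EntityClass.CHEMICAL:
            raise ValidationError("chemical slot must hold a CHEMICAL mention")

    def validate(self) -> None:
        self.plant.validate_against(self.sentence.text)
        self.chemical.validate_against(self.sentence.text)
        if self.label is Label.POS:
            if not self.weak_trigger:
                raise ValidationError("POS unit is missing its weak trigger")
            if not self.strong_trigger:
                raise ValidationError("POS unit is missing its strong trigger")
            if len(self.strong_trigger.split()) != 1:
                raise ValidationError(
                    f"strong trigger {self.strong_trigger!r} must be exactly "
                    "one whitespace-delimited word"
                )
        elif self.label is Label.NEG:
            if self.weak_trigger or self.strong_trigger:
                raise ValidationError("NEG unit must not carry triggers")

    def __eq__(self, other: object) -> bool:
        # doc_offset is deliberately excluded: the annotation sheet has no
        # sentence-offset column, and unit identity is defined by content.
        if not isinstance(other, CorpusUnit):
            return NotImplemented
        return (
            self.sentence.pmid == other.sentence.pmid
            and self.sentence.text == other.sentence.text
            and self.plant == other.plant
            and self.chemical == other.chemical
            and self.label == other.label
            and (self.weak_trigger or None) == (other.weak_trigger or None)
            and (self.strong_trigger or None) == (other.strong_trigger or None)
            and self.provenance == other.provenance
        )


def _pct(num: int, den: int) -> float:
    from .metrics import round_pct

    return round_pct(100.0 * num / den) if den else 0.0


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with derived precision/recall/F1 percentages."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def f1(self) -> float:
        p = 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        r = 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        if p + r == 0:
            return 0.0
        from .metrics import round_pct

        return round_pct(2 * p * r / (p + r))
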