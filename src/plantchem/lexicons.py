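"""Name and trigger lexicons.

Two lexicon kinds feed the pipeline:

* **Name lexicons** map surface terms (possibly multi-word, e.g.
  "Punica granatum") to database identifiers and drive the dictionary NER.
  The packaged fixture lexicons cover every plant/chemical surface form used
  by the worked examples and the synthetic generator; a production run would
  load a full gazetteer in the same one-term-per-line format.
* **The trigger lexicon** holds the verb forms that license a containment
  reading, split by grammatical role: active transitives ("contains"),
  passive past participles ("obtained" — the same set serves the relative
  rule's participles), the intransitives "consist"/"consists", and gerunds
  ("containing").  Triggers are matched on lowercased surface tokens, not
  lemmas, because the word lists enumerate inflected forms explicitly.

Prepositional, apposition and copula triggers are structural (dependency
labels ``prep``/``appos``/``cop``), and the compound-noun trigger is a bare
whitespace, so none of them need a word list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

from .errors import CorpusParseError, ValidationError
from .model import EntityClass, allowed_namespaces

__all__ = [
    "NameLexicon",
    "TriggerLexicon",
    "load_name_lexicon",
    "load_trigger_lexicon",
    "default_triggers",
    "fixture_plant_lexicon",
    "fixture_chemical_lexicon",
]

_TRIGGER_SECTIONS = ("active", "passive", "intransitive", "gerund")


@dataclass
class NameLexicon:
    """Surface term -> identifier list, for one entity class."""

    entity_class: EntityClass
    entries: dict[str, tuple[tuple[str, str], ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, term: str, ids: Iterable[tuple[str, str]]) -> None:
        term = " ".join(term.split())
        if not term:
            raise ValidationError("lexicon term is empty after normalization")
        allowed = allowed_namespaces(self.entity_class)
        for ns, _ in ids:
            if ns not in allowed:
                raise ValidationError(
                    f"namespace {ns!r} not allowed for a "
                    f"{self.entity_class.value} lexicon "
                    f"(guideline allows {sorted(allowed)} or NA)"
                )
        merged = dict.fromkeys(self.entries.get(term, ()))
        merged.update(dict.fromkeys(tuple(ids)))
        self.entries[term] = tuple(sorted(merged))


@dataclass(frozen=True)
class TriggerLexicon:
    """Trigger word sets keyed by grammatical role.

    ``passive`` doubles as the relative rule's past-participle set (the two
    lists are identical by construction).
    """

    active: frozenset[str] = frozenset()
    passive: frozenset[str] = frozenset()
    intransitive: frozenset[str] = frozenset()
    gerund: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in _TRIGGER_SECTIONS:
            for word in getattr(self, name):
                if word != word.lower() or len(word.split()) != 1:
                    raise ValidationError(
                        f"trigger {word!r} must be a lowercase single token"
                    )

    @property
    def past_participle(self) -> frozenset[str]:
        return self.passive

    def without(self, word: str) -> "TriggerLexicon":
        """A copy with ``word`` removed from every set (for ablations)."""
        return TriggerLexicon(
            **{
                name: frozenset(getattr(self, name) - {word})
                for name in _TRIGGER_SECTIONS
            }
        )

    @classmethod
    def empty(cls) -> "TriggerLexicon":
        return cls()


def load_name_lexicon(
    source: str | Path | TextIO, entity_class: EntityClass
) -> NameLexicon:
    """Load a ``term<TAB>namespace:id`` lexicon file.

    Lines starting with ``#`` are ignored; the id field may be ``NA``.
    Duplicate (term, id) pairs are deduplicated; terms are whitespace
    normalized.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return load_name_lexicon(fh, entity_class)
    lex = NameLexicon(entity_class=entity_class)
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        term, _, id_field = line.partition("\t")
        id_field = id_field.strip()
        if id_field in ("", "NA"):
            ids: list[tuple[str, str]] = []
        else:
            ids = []
            for chunk in id_field.split("|"):
                ns, sep, value = chunk.partition(":")
                if not sep or not value:
                    raise CorpusParseError(
                        f"line {lineno}: identifier {chunk!r} is not namespace:id"
                    )
                ids.append((ns.strip(), value.strip()))
        lex.add(term, ids)
    return lex


def _parse_trigger_file(source: TextIO) -> TriggerLexicon:
    sets: dict[str, set[str]] = {name: set() for name in _TRIGGER_SECTIONS}
    current: str | None = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in sets:
                raise CorpusParseError(
                    f"line {lineno}: unknown trigger section {section!r} "
                    f"(expected one of {_TRIGGER_SECTIONS})"
                )
            current = section
            continue
        if current is None:
            raise CorpusParseError(f"line {lineno}: trigger word before any section")
        for word in line.replace(",", " ").split():
            sets[current].add(word.lower())
    return TriggerLexicon(**{k: frozenset(v) for k, v in sets.items()})


def load_trigger_lexicon(source: str | Path | TextIO | None = None) -> TriggerLexicon:
    """Load a sectioned trigger file; defaults to the packaged word lists."""
    if source is None:
        return default_triggers()
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return _parse_trigger_file(fh)
    return _parse_trigger_file(source)


def _packaged(name: str):
    return resources.files("plantchem.data").joinpath(name)


def default_triggers() -> TriggerLexicon:
    """The packaged trigger word lists used by the rule-based model."""
    with _packaged("triggers.txt").open(encoding="utf-8") as fh:
        return _parse_trigger_file(fh)


def fixture_plant_lexicon() -> NameLexicon:
    with _packaged("plants_fixture.tsv").open(encoding="utf-8") as fh:
        return load_name_lexicon(fh, EntityClass.PLANT)


def fixture_chemical_lexicon() -> NameLexicon:
    with _packaged("chemicals_fixture.tsv").open(encoding="utf-8") as fh:
        return load_name_lexicon(fh, EntityClass.CHEMICAL)
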