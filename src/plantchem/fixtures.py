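"""Worked-example fixtures and the synthetic corpus generator.

Two sources of fully-specified test corpora, both parser-independent:

* :func:`worked_examples` packages the rule-development worked examples —
  one sentence per rule structure, each with a hand-built gold dependency
  parse — plus four documented model-error sentences: two solvent/treatment
  contexts the purely syntactic model wrongly predicts POS, and two
  constructions ("plant-specific chemical", a parenthesised plant source)
  it has no structure for and wrongly predicts NEG.
* :func:`generate` builds seeded synthetic corpora from sentence templates
  (one per rule structure, trigger-free negatives, and confounder templates
  mimicking the documented false-positive contexts).  Every generated
  sentence carries a programmatically constructed gold parse consistent
  with its template, so the rule engine can be tested at scale offline.

The generator emulates the *structural* variety of the corpus (one template
per rule structure, a balanced class mix by default) with single-token
entity names drawn from the worked examples' vocabulary.  It does not
emulate real abstracts' lexical diversity, parser noise, or the corpus's
empirical class ratio.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from importlib import resources

from .corpus_io import docs_from_units
from .depgraph import DependencyGraph, graph_from_rows, read_conll
from .errors import IntegrityError
from .model import (
    AbstractDoc,
    CorpusUnit,
    EntityClass,
    EntityMention,
    Label,
    SentenceRecord,
)

__all__ = ["FixtureUnit", "worked_examples", "generate", "fixture_docs", "fixture_parses"]


@dataclass
class FixtureUnit:
    """A corpus unit bundled with its gold parse and expected behaviour.

    ``gold_label`` is the annotation; ``expected_model_label`` is what the
    rule engine should predict (they differ exactly for the documented-error
    confounders).  ``expected_rule_id`` names the structure expected to be
    reported first, when one is expected at all.
    """

    unit: CorpusUnit
    graph: DependencyGraph
    gold_label: Label
    expected_model_label: Label
    expected_rule_id: str | None
    template_id: str

    @property
    def is_confounder(self) -> bool:
        return self.gold_label != self.expected_model_label


def _load_gold_parses() -> dict[str, tuple[str, DependencyGraph]]:
    res = resources.files("plantchem.data").joinpath("gold_parses.conll")
    raw = res.read_text(encoding="utf-8")
    ids = re.findall(r"^# id = (\S+)", raw, flags=re.MULTILINE)
    import io

    parses = read_conll(io.StringIO(raw))
    if len(ids) != len(parses):
        raise IntegrityError("gold parse file: id comments do not match blocks")
    return dict(zip(ids, parses))


# fixture id, pmid, plant surface, chemical surface, gold label,
# expected model label, expected rule id, weak trigger, strong trigger
_EXAMPLE_META = [
    ("V1", "15493960", "Pomegranate", "anthocyanins", "POS", "POS", "V1",
     ("contains",), "contains"),
    ("V2", "23605447", "corn", "FB1", "POS", "POS", "V2",
     ("were", "obtained", "from"), "obtained"),
    ("V3", "17637489", "ginger", "sesquiterpenes", "POS", "POS", "V3",
     ("consists", "of"), "consists"),
    ("P1", "22354956", "Switchgrass", "carbon", "POS", "POS", "P1",
     ("as",), "as"),
    ("P2", "20518315", "Panax notoginseng", "Saponins", "POS", "POS", "P2",
     ("from",), "from"),
    ("R1", "16457818", "black soybean", "Anthocyanins", "POS", "POS", "R1",
     ("isolated", "from"), "isolated"),
    ("R2", "11603284", "Feverfew", "parthenolide", "POS", "POS", "R2",
     ("containing",), "containing"),
    ("A1", "19932903", "soybean oil", "fatty acids", "POS", "POS", "A1",
     (",",), ","),
    ("A2", "9129126", "marijuana", "Delta9-tetrahydrocannabinol", "POS", "POS",
     "A2", (",",), ","),
    ("C1", "23605447", "Haematococcus pluvialis", "astaxanthin", "POS", "POS",
     "C1", ("is",), "is"),
    ("C2", "21695915", "papaya", "calcium", "POS", "POS", "C2",
     ("were", "the", "highest", "in"), "in"),
    ("CN1", "19317166", "panax notoginseng", "saponins", "POS", "POS", "CN1",
     ("notoginseng", "saponins"), "saponins"),
    # Documented model errors: syntactic false positives ...
    ("FP_EXTRACT", "90000001", "Feverfew", "dichloromethane", "NEG", "POS",
     "P2", None, None),
    ("FP_TREATMENT", "90000002", "rice", "Ammonia", "NEG", "POS", "P2",
     None, None),
    # ... and out-of-grammar false negatives.
    ("FN_SPECIFIC", "90000003", "tobacco", "nitrosamines", "POS", "NEG", None,
     ("-specific",), "-specific"),
    ("FN_BRACKET", "90000004", "potato", "3-(methylthio)propanal", "POS",
     "NEG", None, ("(cooked", "potato)"), "(cooked"),
]


def _mention(text: str, surface: str, cls: EntityClass) -> EntityMention:
    start = text.find(surface)
    if start < 0:
        raise IntegrityError(f"surface {surface!r} not in fixture sentence")
    return EntityMention(
        entity_class=cls, start=start, end=start + len(surface), text=surface
    )


def worked_examples() -> list[FixtureUnit]:
    """The 12 worked-example units (one per rule structure; the V2 sentence
    is the passive-clause parse example) plus 4 documented-error units."""
    parses = _load_gold_parses()
    out: list[FixtureUnit] = []
    for (fid, pmid, plant_sf, chem_sf, gold, expected, rule_id, weak,
         strong) in _EXAMPLE_META:
        text, graph = parses[fid]
        sent = SentenceRecord(doc_offset=0, text=text, pmid=pmid)
        plant = _mention(text, plant_sf, EntityClass.PLANT)
        chem = _mention(text, chem_sf, EntityClass.CHEMICAL)
        sent.mentions = sorted(
            [plant, chem], key=lambda m: (m.start, m.end, m.entity_class.value)
        )
        unit = CorpusUnit(
            sentence=sent,
            plant=plant,
            chemical=chem,
            label=Label(gold),
            weak_trigger=weak,
            strong_trigger=strong,
        )
        unit.validate()
        sent.units = [unit]  # type: ignore[attr-defined]
        out.append(
            FixtureUnit(
                unit=unit,
                graph=graph,
                gold_label=Label(gold),
                expected_model_label=Label(expected),
                expected_rule_id=rule_id,
                template_id=fid,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic templates.  Each template returns CoNLL-style rows
# (form, 1-based head, deprel) plus the plant/chemical token indices
# (0-based) and the weak/strong triggers for POS sentences.
# ---------------------------------------------------------------------------

_PLANT_POOL = (
    "ginger", "switchgrass", "papaya", "corn", "rice", "tobacco", "potato",
    "aloe", "cucumber", "tomato", "marijuana", "soybean",
)
_CHEM_POOL = (
    "anthocyanins", "sesquiterpenes", "parthenolide", "astaxanthin",
    "calcium", "nitrogen", "saponins", "emodin", "carbon", "ammonia",
)
_SOLVENT_POOL = ("dichloromethane", "methanol", "ethanol", "chloroform", "isopropanol")

_V1_TRIGGERS = ("contains", "includes", "comprises", "produces", "has")
_V2_TRIGGERS = ("obtained", "isolated", "extracted", "derived")
_R1_TRIGGERS = ("isolated", "extracted", "obtained")
_R2_TRIGGERS = ("containing", "including", "comprising")


def _t_v1(p, c, rng):
    tw = rng.choice(_V1_TRIGGERS)
    rows = [(p, 2, "nsubj"), (tw, 0, "root"), (c, 2, "dobj"), (".", 2, "punct")]
    return rows, [0], [2], (tw,), tw


def _t_v2(p, c, rng):
    tw = rng.choice(_V2_TRIGGERS)
    rows = [
        (c, 3, "nsubjpass"), ("was", 3, "auxpass"), (tw, 0, "root"),
        ("from", 3, "prep"), (p, 4, "pobj"), (".", 3, "punct"),
    ]
    return rows, [4], [0], ("was", tw, "from"), tw


def _t_v3(p, c, rng):
    rows = [
        (p, 2, "nsubj"), ("consists", 0, "root"), ("of", 2, "prep"),
        (c, 3, "pobj"), (".", 2, "punct"),
    ]
    return rows, [0], [3], ("consists", "of"), "consists"


def _t_p1(p, c, rng):
    rows = [
        (p, 0, "root"), ("as", 1, "prep"), ("a", 5, "det"), (c, 5, "nn"),
        ("source", 2, "pobj"), (".", 1, "punct"),
    ]
    return rows, [0], [3], ("as",), "as"


def _t_p2(p, c, rng):
    rows = [
        (c, 0, "root"), ("from", 1, "prep"), ("the", 4, "det"),
        ("leaves", 2, "pobj"), ("of", 4, "prep"), (p, 5, "pobj"),
        (".", 1, "punct"),
    ]
    return rows, [5], [0], ("from",), "from"


def _t_r1(p, c, rng):
    tw = rng.choice(_R1_TRIGGERS)
    rows = [
        (c, 0, "root"), (tw, 1, "partmod"), ("from", 2, "prep"),
        (p, 6, "nn"), ("seed", 6, "nn"), ("coat", 3, "pobj"), (".", 1, "punct"),
    ]
    return rows, [3], [0], (tw, "from"), tw


def _t_r2(p, c, rng):
    tw = rng.choice(_R2_TRIGGERS)
    rows = [
        (p, 2, "nn"), ("powder", 6, "nsubjpass"), (tw, 2, "partmod"),
        (c, 3, "dobj"), ("was", 6, "auxpass"), ("studied", 0, "root"),
        (".", 6, "punct"),
    ]
    return rows, [0], [3], (tw,), tw


def _t_a1(p, c, rng):
    rows = [
        (p, 9, "nsubjpass"), (",", 1, "punct"), ("a", 4, "det"),
        ("source", 1, "appos"), ("of", 4, "prep"), (c, 5, "pobj"),
        (",", 1, "punct"), ("was", 9, "auxpass"), ("studied", 0, "root"),
        (".", 9, "punct"),
    ]
    return rows, [0], [5], (",",), ","


def _t_a2(p, c, rng):
    rows = [
        (c, 9, "nsubjpass"), (",", 1, "punct"), ("a", 4, "det"),
        ("component", 1, "appos"), ("of", 4, "prep"), (p, 5, "pobj"),
        (",", 1, "punct"), ("was", 9, "auxpass"), ("studied", 0, "root"),
        (".", 9, "punct"),
    ]
    return rows, [5], [0], (",",), ","


def _t_c1(p, c, rng):
    rows = [
        (p, 4, "nsubj"), ("is", 4, "cop"), ("a", 4, "det"),
        ("source", 0, "root"), ("of", 4, "prep"), (c, 5, "pobj"),
        (".", 4, "punct"),
    ]
    return rows, [0], [5], ("is",), "is"


def _t_c2(p, c, rng):
    rows = [
        ("The", 3, "det"), (c, 3, "nn"), ("contents", 5, "nsubj"),
        ("were", 5, "cop"), ("highest", 0, "root"), ("in", 5, "prep"),
        ("the", 8, "det"), (p, 6, "pobj"), (".", 5, "punct"),
    ]
    return rows, [7], [1], ("were", "highest", "in"), "in"


def _t_cn1(p, c, rng):
    rows = [
        (p, 3, "nn"), (c, 3, "nn"), ("extract", 5, "nsubjpass"),
        ("was", 5, "auxpass"), ("studied", 0, "root"), (".", 5, "punct"),
    ]
    return rows, [0], [1], (p, c), c


def _t_n1(p, c, rng):
    rows = [
        (p, 3, "nsubjpass"), ("was", 3, "auxpass"), ("compared", 0, "root"),
        ("with", 3, "prep"), (c, 6, "nn"), ("treatment", 4, "pobj"),
        (".", 3, "punct"),
    ]
    return rows, [0], [4], None, None


def _t_n2(p, c, rng):
    rows = [
        ("The", 2, "det"), ("effect", 9, "nsubjpass"), ("of", 2, "prep"),
        (c, 3, "pobj"), ("on", 2, "prep"), (p, 7, "nn"),
        ("growth", 5, "pobj"), ("was", 9, "auxpass"), ("studied", 0, "root"),
        (".", 9, "punct"),
    ]
    return rows, [5], [3], None, None


def _t_n3(p, c, rng):
    rows = [
        (p, 2, "nn"), ("growth", 3, "nsubj"), ("requires", 0, "root"),
        (c, 5, "nn"), ("supplementation", 3, "dobj"), (".", 3, "punct"),
    ]
    return rows, [0], [3], None, None


def _t_n4(p, c, rng):
    rows = [
        (c, 3, "nsubjpass"), ("was", 3, "auxpass"), ("applied", 0, "root"),
        ("to", 3, "prep"), (p, 6, "nn"), ("seedlings", 4, "pobj"),
        (".", 3, "punct"),
    ]
    return rows, [4], [0], None, None


def _t_cf_extract(p, c, rng):
    rows = [
        ("The", 3, "det"), (c, 3, "nn"), ("extract", 7, "nsubjpass"),
        ("of", 3, "prep"), (p, 4, "pobj"), ("was", 7, "auxpass"),
        ("tested", 0, "root"), (".", 7, "punct"),
    ]
    return rows, [4], [1], None, None


def _t_cf_treatment(p, c, rng):
    rows = [
        (c, 2, "nn"), ("treatment", 6, "nsubj"), ("of", 2, "prep"),
        (p, 5, "nn"), ("straw", 3, "pobj"), ("improved", 0, "root"),
        ("storage", 6, "dobj"), (".", 6, "punct"),
    ]
    return rows, [3], [0], None, None


_POSITIVE_TEMPLATES = [
    ("V1", _t_v1), ("V2", _t_v2), ("V3", _t_v3), ("P1", _t_p1),
    ("P2", _t_p2), ("R1", _t_r1), ("R2", _t_r2), ("A1", _t_a1),
    ("A2", _t_a2), ("C1", _t_c1), ("C2", _t_c2), ("CN1", _t_cn1),
]
_NEGATIVE_TEMPLATES = [
    ("N1", _t_n1), ("N2", _t_n2), ("N3", _t_n3), ("N4", _t_n4),
]
_CONFOUNDER_TEMPLATES = [
    ("CF_EXTRACT", _t_cf_extract), ("CF_TREATMENT", _t_cf_treatment),
]


def _build_fixture(
    template_id: str,
    builder,
    gold: Label,
    expected: Label,
    expected_rule: str | None,
    pmid: str,
    rng: random.Random,
) -> FixtureUnit:
    plant_name = rng.choice(_PLANT_POOL)
    if template_id == "CF_EXTRACT":
        chem_name = rng.choice(_SOLVENT_POOL)
    else:
        chem_name = rng.choice(_CHEM_POOL)
    rows, plant_toks, chem_toks, weak, strong = builder(plant_name, chem_name, rng)
    text, graph = graph_from_rows(rows)
    sent = SentenceRecord(doc_offset=0, text=text, pmid=pmid)

    def span_of(token_indices: list[int]) -> tuple[int, int]:
        toks = [graph.tokens[i] for i in token_indices]
        return toks[0].start, toks[-1].end

    p_start, p_end = span_of(plant_toks)
    c_start, c_end = span_of(chem_toks)
    plant = EntityMention(
        EntityClass.PLANT, p_start, p_end, text[p_start:p_end]
    )
    chem = EntityMention(
        EntityClass.CHEMICAL, c_start, c_end, text[c_start:c_end]
    )
    sent.mentions = sorted(
        [plant, chem], key=lambda m: (m.start, m.end, m.entity_class.value)
    )
    unit = CorpusUnit(
        sentence=sent,
        plant=plant,
        chemical=chem,
        label=gold,
        weak_trigger=weak if gold is Label.POS else None,
        strong_trigger=strong if gold is Label.POS else None,
    )
    unit.validate()
    sent.units = [unit]  # type: ignore[attr-defined]
    return FixtureUnit(
        unit=unit,
        graph=graph,
        gold_label=gold,
        expected_model_label=expected,
        expected_rule_id=expected_rule,
        template_id=template_id,
    )


def generate(
    n: int,
    positive_fraction: float = 0.5,
    confounder_fraction: float = 0.1,
    seed: int = 0,
) -> list[FixtureUnit]:
    """Generate ``n`` synthetic fixture units with a known class mix.

    Counts are allocated deterministically — ``round(n * fraction)``
    positives and confounders, the remainder trigger-free negatives — and
    the unit order is shuffled by ``seed``.  Positives cycle through the 12
    rule-structure templates, so the realized mix of structures is even.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    for frac in (positive_fraction, confounder_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    n_pos = round(n * positive_fraction)
    n_conf = round(n * confounder_fraction)
    if n_pos + n_conf > n:
        raise ValueError("positive and confounder fractions exceed the corpus")
    n_neg = n - n_pos - n_conf
    rng = random.Random(seed)
    out: list[FixtureUnit] = []
    serial = 0

    def emit(count: int, templates, gold: Label, expected: Label,
             rule_of) -> None:
        nonlocal serial
        for i in range(count):
            template_id, builder = templates[i % len(templates)]
            serial += 1
            out.append(
                _build_fixture(
                    template_id,
                    builder,
                    gold,
                    expected,
                    rule_of(template_id),
                    pmid=f"{90000000 + serial}",
                    rng=rng,
                )
            )

    emit(n_pos, _POSITIVE_TEMPLATES, Label.POS, Label.POS, lambda t: t)
    emit(n_neg, _NEGATIVE_TEMPLATES, Label.NEG, Label.NEG, lambda t: None)
    # Confounders mimic the documented solvent/treatment false positives:
    # both fire the prepositional rule (structure P2).
    emit(n_conf, _CONFOUNDER_TEMPLATES, Label.NEG, Label.POS, lambda t: "P2")
    rng.shuffle(out)
    return out


def fixture_docs(units: list[FixtureUnit]) -> list[AbstractDoc]:
    """Wrap fixture units as single-sentence documents (for BioC export)."""
    return docs_from_units([f.unit for f in units])


def fixture_parses(units: list[FixtureUnit]) -> list[tuple[str, DependencyGraph]]:
    """(sentence text, gold parse) pairs, deduplicated by sentence text."""
    seen: dict[str, DependencyGraph] = {}
    for f in units:
        seen.setdefault(f.unit.sentence.text, f.graph)
    return list(seen.items())
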