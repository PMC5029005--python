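"""The six-family dependency-pattern rule engine.

A corpus unit is predicted POS when at least one of six rule families fires
on the sentence's dependency parse; otherwise NEG.  Writing NP0 for the noun
phrase containing the plant mention and NP1 for the chemical's:

=========  ==========================  =======================================
family     structures                  trigger
=========  ==========================  =======================================
verbal     V1  NP0 Vtr NP1             active transitive ("contains")
           V2  NP1 Vtr PP NP0          passive participle + any preposition
           V3  NP0 Vtr PP NP1          intransitive ("consists") + preposition
preposit.  P1  NP0 PPtr NP1            any token governed by a ``prep`` edge
           P2  NP1 PPtr NP0            attached inside the first NP
relative   R1  NP1 Rtr PP NP0          past participle modifying the NP1 head
           R2  NP0 Rtr (PP) NP1        gerund modifying the NP0 head
                                       ("consisting" requires "of")
apposition A1  NP0 APtr NP1            any ``appos`` edge; token distance
           A2  NP1 APtr NP0            between the NPs below ``max_dist``
copula     C1  NP0 Ctr NP1             any ``cop`` edge; same distance bound
           C2  NP1 Ctr NP0
compound   CN1 NP0 CNtr NP1            a single whitespace between the plant
                                       mention's end and the chemical's start
=========  ==========================  =======================================

An entity is "inside" an NP when its head token lies in the NP's subtree.
Families are evaluated in the fixed order V, P, R, A, C, CN; the order only
decides which match is reported first — the POS/NEG prediction is the same
under any order.  The engine is purely syntactic: solvent, pesticide and
other semantic contexts that merely look like containment are (by design)
predicted POS, and structures outside the table (e.g. "plant-specific
chemical") are predicted NEG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .depgraph import (
    DependencyGraph,
    NounPhrase,
    mention_head,
    nominal_head,
    np_subtree,
    token_distance,
)
from .errors import IntegrityError
from .lexicons import TriggerLexicon
from .model import CorpusUnit, Label

__all__ = [
    "RuleMatch",
    "match_verbal",
    "match_prepositional",
    "match_relative",
    "match_apposition",
    "match_copula",
    "match_compound",
    "classify_unit",
    "ALL_FAMILIES",
    "DEFAULT_MAX_DIST",
]

#: Family evaluation order (decides the reported match, not the label).
ALL_FAMILIES = ("V", "P", "R", "A", "C", "CN")

#: Apposition/copula token-distance bound: strictly fewer than this many
#: tokens may separate the two NPs.
DEFAULT_MAX_DIST = 10

_PARTICIPLE_LABELS = ("partmod", "amod")


@dataclass(frozen=True)
class RuleMatch:
    """A fired rule: structure id, trigger token indices, and the two NPs.

    ``trigger_tokens`` is empty only for CN1, whose trigger is a bare
    whitespace.  NPs may be None for CN1 (character-level rule).
    """

    rule_id: str
    trigger_tokens: tuple[int, ...]
    np_plant: NounPhrase | None = None
    np_chemical: NounPhrase | None = None

    @property
    def family(self) -> str:
        return "CN" if self.rule_id.startswith("CN") else self.rule_id[0]


def _np_of(graph: DependencyGraph, head: int) -> NounPhrase:
    return np_subtree(graph, nominal_head(graph, head))


def match_verbal(
    graph: DependencyGraph,
    plant_head: int,
    chem_head: int,
    triggers: TriggerLexicon,
) -> RuleMatch | None:
    """V1/V2/V3: trigger verb linking subject and object/prepositional NPs."""
    for v in range(len(graph)):
        word = graph.token_text(v)
        if word in triggers.active:
            for s in graph.children_with(v, "nsubj"):
                if plant_head not in graph.subtree(s):
                    continue
                for o in graph.children_with(v, "dobj"):
                    if chem_head in graph.subtree(o):
                        return RuleMatch(
                            "V1",
                            (v,),
                            np_plant=np_subtree(graph, s),
                            np_chemical=np_subtree(graph, o),
                        )
        if word in triggers.passive:
            for s in graph.children_with(v, "nsubjpass"):
                if chem_head not in graph.subtree(s):
                    continue
                for p in graph.children_with(v, "prep"):
                    for o in graph.children_with(p, "pobj"):
                        if plant_head in graph.subtree(o):
                            return RuleMatch(
                                "V2",
                                (v, p),
                                np_plant=np_subtree(graph, o),
                                np_chemical=np_subtree(graph, s),
                            )
        if word in triggers.intransitive:
            for s in graph.children_with(v, "nsubj"):
                if plant_head not in graph.subtree(s):
                    continue
                for p in graph.children_with(v, "prep"):
                    for o in graph.children_with(p, "pobj"):
                        if chem_head in graph.subtree(o):
                            return RuleMatch(
                                "V3",
                                (v, p),
                                np_plant=np_subtree(graph, s),
                                np_chemical=np_subtree(graph, o),
                            )
    return None


def match_prepositional(
    graph: DependencyGraph, plant_head: int, chem_head: int
) -> RuleMatch | None:
    """P1/P2: a preposition attached inside one entity's NP whose object
    subtree contains the other entity."""
    cases = (
        ("P1", plant_head, chem_head),
        ("P2", chem_head, plant_head),
    )
    for rule_id, first, second in cases:
        np_first = _np_of(graph, first)
        for h, p, label in graph.edges():
            if label != "prep" or h not in np_first.members:
                continue
            if first in graph.subtree(p):
                continue
            for o in graph.children_with(p, "pobj"):
                if second in graph.subtree(o):
                    plant_np = np_first if rule_id == "P1" else np_subtree(graph, o)
                    chem_np = np_subtree(graph, o) if rule_id == "P1" else np_first
                    return RuleMatch(
                        rule_id, (p,), np_plant=plant_np, np_chemical=chem_np
                    )
    return None


def match_relative(
    graph: DependencyGraph,
    plant_head: int,
    chem_head: int,
    triggers: TriggerLexicon,
) -> RuleMatch | None:
    """R1/R2: participle or gerund modifying one entity's NP head."""
    for noun, mod, label in graph.edges():
        if label not in _PARTICIPLE_LABELS:
            continue
        word = graph.token_text(mod)
        if word in triggers.past_participle and chem_head in np_subtree(graph, noun).members:
            for p in graph.children_with(mod, "prep"):
                for o in graph.children_with(p, "pobj"):
                    if plant_head in graph.subtree(o):
                        return RuleMatch(
                            "R1",
                            (mod, p),
                            np_plant=np_subtree(graph, o),
                            np_chemical=np_subtree(graph, noun),
                        )
        if word in triggers.gerund and plant_head in np_subtree(graph, noun).members:
            if word == "consisting":
                # intransitive gerund: the object must come via "of"
                for p in graph.children_with(mod, "prep"):
                    if graph.token_text(p) != "of":
                        continue
                    for o in graph.children_with(p, "pobj"):
                        if chem_head in graph.subtree(o):
                            return RuleMatch(
                                "R2",
                                (mod, p),
                                np_plant=np_subtree(graph, noun),
                                np_chemical=np_subtree(graph, o),
                            )
            else:
                for o in graph.children_with(mod, "dobj"):
                    if chem_head in graph.subtree(o):
                        return RuleMatch(
                            "R2",
                            (mod,),
                            np_plant=np_subtree(graph, noun),
                            np_chemical=np_subtree(graph, o),
                        )
    return None


def match_apposition(
    graph: DependencyGraph,
    plant_head: int,
    chem_head: int,
    max_dist: int = DEFAULT_MAX_DIST,
) -> RuleMatch | None:
    """A1/A2: the entities sit in two apposed NPs within the distance bound."""
    for g, d in graph.edges_with("appos"):
        gov_side = graph.subtree(g) - graph.subtree(d)
        dep_side = graph.subtree(d)
        if plant_head in gov_side and chem_head in dep_side:
            rule_id = "A1"
        elif chem_head in gov_side and plant_head in dep_side:
            rule_id = "A2"
        else:
            continue
        np_gov = NounPhrase(
            head=g, members=frozenset(np_subtree(graph, g).members - dep_side)
        )
        np_dep = np_subtree(graph, d)
        if token_distance(np_gov, np_dep) < max_dist:
            plant_np = np_gov if rule_id == "A1" else np_dep
            chem_np = np_dep if rule_id == "A1" else np_gov
            return RuleMatch(rule_id, (d,), np_plant=plant_np, np_chemical=chem_np)
    return None


def match_copula(
    graph: DependencyGraph,
    plant_head: int,
    chem_head: int,
    max_dist: int = DEFAULT_MAX_DIST,
) -> RuleMatch | None:
    """C1/C2: subject and copular predicate NPs within the distance bound.

    Any verb with a ``cop`` edge counts (every tense of "be").
    """
    for pred, cop in graph.edges_with("cop"):
        for s in graph.children_with(pred, "nsubj"):
            subj_side = graph.subtree(s)
            pred_side = graph.subtree(pred) - subj_side - {cop}
            if plant_head in subj_side and chem_head in pred_side:
                rule_id = "C1"
            elif chem_head in subj_side and plant_head in pred_side:
                rule_id = "C2"
            else:
                continue
            np_subj = np_subtree(graph, s)
            np_pred = NounPhrase(
                head=pred,
                members=frozenset(
                    np_subtree(graph, pred).members - subj_side - {cop}
                ),
            )
            if token_distance(np_subj, np_pred) < max_dist:
                plant_np = np_subj if rule_id == "C1" else np_pred
                chem_np = np_pred if rule_id == "C1" else np_subj
                return RuleMatch(
                    rule_id, (cop,), np_plant=plant_np, np_chemical=chem_np
                )
    return None


def match_compound(unit: CorpusUnit) -> RuleMatch | None:
    """CN1: plant mention, one whitespace, chemical mention — in that order."""
    between = unit.sentence.text[unit.plant.end : unit.chemical.start]
    if unit.plant.end < unit.chemical.start and between == " ":
        return RuleMatch("CN1", ())
    return None


def classify_unit(
    graph: DependencyGraph,
    unit: CorpusUnit,
    triggers: TriggerLexicon,
    max_dist: int = DEFAULT_MAX_DIST,
    families: Iterable[str] = ALL_FAMILIES,
) -> tuple[Label, list[RuleMatch]]:
    """Predict POS/NEG for a corpus unit and report all fired matches.

    The unit's mentions must align to the graph's tokens (same sentence
    text); a misalignment raises :class:`IntegrityError`.
    """
    if graph.text is not None and graph.text != unit.sentence.text:
        raise IntegrityError(
            "corpus unit sentence does not match the parse's sentence text"
        )
    plant_head = mention_head(graph, unit.plant)
    chem_head = mention_head(graph, unit.chemical)
    matchers = {
        "V": lambda: match_verbal(graph, plant_head, chem_head, triggers),
        "P": lambda: match_prepositional(graph, plant_head, chem_head),
        "R": lambda: match_relative(graph, plant_head, chem_head, triggers),
        "A": lambda: match_apposition(graph, plant_head, chem_head, max_dist),
        "C": lambda: match_copula(graph, plant_head, chem_head, max_dist),
        "CN": lambda: match_compound(unit),
    }
    matches: list[RuleMatch] = []
    for family in ALL_FAMILIES:
        if family not in tuple(families):
            continue
        m = matchers[family]()
        if m is not None:
            matches.append(m)
    label = Label.POS if matches else Label.NEG
    return label, matches
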