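import random

import pytest

from plantchem.depgraph import graph_from_rows, mention_head
from plantchem.errors import IntegrityError
from plantchem.fixtures import generate, worked_examples
from plantchem.lexicons import TriggerLexicon
from plantchem.model import CorpusUnit, EntityClass, EntityMention, Label, SentenceRecord
from plantchem.rules import (
    classify_unit,
    match_apposition,
    match_compound,
    match_copula,
    match_relative,
    match_verbal,
)


def heads(fixture):
    g = fixture.graph
    return (
        mention_head(g, fixture.unit.plant),
        mention_head(g, fixture.unit.chemical),
    )


def unit_from_rows(rows, plant_tok, chem_tok):
    text, graph = graph_from_rows(rows)
    sent = SentenceRecord(0, text)
    toks = graph.tokens

    def m(cls, i):
        return EntityMention(cls, toks[i].start, toks[i].end, toks[i].text)

    plant = m(EntityClass.PLANT, plant_tok)
    chem = m(EntityClass.CHEMICAL, chem_tok)
    sent.mentions = sorted([plant, chem], key=lambda x: x.start)
    return graph, CorpusUnit(sentence=sent, plant=plant, chemical=chem)


@pytest.mark.parametrize("fixture", worked_examples(), ids=lambda f: f.template_id)
def test_each_worked_example_fires_its_own_rule(fixture, triggers):
    label, matches = classify_unit(fixture.graph, fixture.unit, triggers)
    assert label is fixture.expected_model_label
    reported = matches[0].rule_id if matches else None
    assert reported == fixture.expected_rule_id


def test_passive_clause_example_triggers(examples, triggers):
    """The passive worked example fires the passive verbal structure with
    trigger tokens 'obtained' + 'from'."""
    f = examples["V2"]
    _, matches = classify_unit(f.graph, f.unit, triggers)
    m = matches[0]
    assert m.rule_id == "V2"
    words = [f.graph.tokens[i].text for i in m.trigger_tokens]
    assert words == ["obtained", "from"]
    # the subject NP of the passive clause is the chemical's NP
    assert f.graph.tokens[m.np_chemical.head].text == "mg"


def test_removing_the_trigger_kills_the_verbal_match(examples, triggers):
    f = examples["V2"]
    plant_head, chem_head = heads(f)
    assert match_verbal(f.graph, plant_head, chem_head, triggers) is not None
    ablated = triggers.without("obtained")
    assert match_verbal(f.graph, plant_head, chem_head, ablated) is None
    label, _ = classify_unit(f.graph, f.unit, ablated)
    assert label is Label.NEG


def test_consisting_requires_of():
    rows = [
        ("Feverfew", 2, "nn"), ("powder", 0, "root"),
        ("consisting", 2, "partmod"), ("parthenolide", 3, "dobj"),
    ]
    graph, unit = unit_from_rows(rows, 0, 3)
    triggers = TriggerLexicon(gerund=frozenset({"consisting"}))
    assert match_relative(graph, 0, 3, triggers) is None
    # with "of" the same structure fires
    rows_of = [
        ("Feverfew", 2, "nn"), ("powder", 0, "root"),
        ("consisting", 2, "partmod"), ("of", 3, "prep"),
        ("parthenolide", 4, "pobj"),
    ]
    graph2, _ = unit_from_rows(rows_of, 0, 4)
    m = match_relative(graph2, 0, 4, triggers)
    assert m is not None and m.rule_id == "R2"


def test_apposition_beyond_distance_bound_is_rejected():
    # 12 relative-clause tokens (outside both NPs) between the apposed NPs
    rows = [("ginseng", 0, "root")]
    rows += [(f"f{i}", 1, "rcmod") for i in range(12)]
    rows += [
        (",", 1, "punct"), ("a", 16, "det"), ("source", 1, "appos"),
        ("of", 16, "prep"), ("saponins", 17, "pobj"),
    ]
    graph, unit = unit_from_rows(rows, 0, 17)
    assert match_apposition(graph, 0, 17) is None
    assert match_apposition(graph, 0, 17, max_dist=20) is not None


def test_copula_needs_one_entity_in_predicate(examples):
    graph = examples["C2"].graph
    calcium, contents = 1, 2
    # both query heads inside the subject NP: no copular relation
    assert match_copula(graph, contents, calcium) is None


def test_compound_noun_requires_plant_first():
    rows = [
        ("saponins", 2, "nn"), ("panax", 0, "root"), (".", 2, "punct"),
    ]
    _, unit = unit_from_rows(rows, 1, 0)
    assert match_compound(unit) is None
    rows = [("Aloe", 2, "nn"), ("emodin", 0, "root"), (".", 2, "punct")]
    _, unit = unit_from_rows(rows, 0, 1)
    m = match_compound(unit)
    assert m is not None and m.rule_id == "CN1" and m.trigger_tokens == ()


def test_structural_rules_disabled_and_empty_lexicon_predict_all_neg():
    empty = TriggerLexicon.empty()
    for f in generate(60, 0.6, 0.2, seed=17):
        label, matches = classify_unit(
            f.graph, f.unit, empty, families=("V", "R")
        )
        assert label is Label.NEG and matches == []


def test_trigger_removal_is_monotone():
    """Shrinking the trigger lexicon never flips a NEG prediction to POS."""
    from plantchem.lexicons import default_triggers

    triggers = default_triggers()
    fixtures = generate(60, 0.5, 0.1, seed=23)
    base = [classify_unit(f.graph, f.unit, triggers)[0] for f in fixtures]
    vocab = sorted(triggers.active | triggers.passive | triggers.gerund
                   | triggers.intransitive)
    for word in random.Random(0).sample(vocab, 12):
        ablated = triggers.without(word)
        for f, base_label in zip(fixtures, base):
            new_label, _ = classify_unit(f.graph, f.unit, ablated)
            assert not (base_label is Label.NEG and new_label is Label.POS)


def test_classification_is_pure(examples, triggers):
    f = examples["C1"]
    first = classify_unit(f.graph, f.unit, triggers)
    second = classify_unit(f.graph, f.unit, triggers)
    assert first == second


def test_misaligned_unit_raises(examples, triggers):
    f1, f2 = examples["V1"], examples["V2"]
    with pytest.raises(IntegrityError):
        classify_unit(f1.graph, f2.unit, triggers)


def test_documented_error_fixtures_reproduce_model_behaviour(examples, triggers):
    # syntactic false positives: solvent extract and treatment contexts
    for fid in ("FP_EXTRACT", "FP_TREATMENT"):
        f = examples[fid]
        label, matches = classify_unit(f.graph, f.unit, triggers)
        assert f.gold_label is Label.NEG
        assert label is Label.POS
        assert matches[0].rule_id == "P2"
    # out-of-grammar false negatives
    for fid in ("FN_SPECIFIC", "FN_BRACKET"):
        f = examples[fid]
        label, matches = classify_unit(f.graph, f.unit, triggers)
        assert f.gold_label is Label.POS
        assert label is Label.NEG and matches == []
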