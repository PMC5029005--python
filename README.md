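# plantchem

Rule-based extraction of **plant–chemical containment relationships** from
biomedical text, plus the corpus-construction tooling around it.

Plants are a major source of bioactive compounds, and statements like
*"Pomegranate contains anthocyanins"* are scattered across millions of
PubMed abstracts. `plantchem` mines such statements at the sentence level:
it recognises plant and chemical names with a dictionary matcher, keeps the
sentences where both co-occur, expands every (plant, chemical) mention pair
into a *corpus unit*, and labels each unit **POS** (the plant contains /
yields the chemical) or **NEG** (no containment stated) with a purely
syntactic rule engine over Stanford-style dependency parses.

## The model

Writing NP₀ for the noun phrase containing the plant mention and NP₁ for
the chemical's, a unit is POS when any of six rule families matches the
sentence's dependency parse:

| family | structures | trigger |
|---|---|---|
| verbal | NP₀ V_tr NP₁ · NP₁ V_tr PP NP₀ · NP₀ V_tr PP NP₁ | transitive active ("contains"), passive participle + preposition ("were obtained from"), intransitive + preposition ("consists of") |
| prepositional | NP₀ PP_tr NP₁ · NP₁ PP_tr NP₀ | any `prep` token attached inside the first NP |
| relative | NP₁ R_tr PP NP₀ · NP₀ R_tr (PP) NP₁ | past participle ("isolated from") or gerund ("containing"; "consisting" requires "of") |
| apposition | NP₀ AP_tr NP₁ · NP₁ AP_tr NP₀ | any `appos` edge, < 10 tokens between the NPs |
| copula | NP₀ C_tr NP₁ · NP₁ C_tr NP₀ | any `cop` edge (every tense of *be*), same distance bound |
| compound noun | NP₀ CN_tr NP₁ | a single whitespace ("Aloe emodin") |

Trigger verbs come from a curated word list (packaged); prepositional,
apposition and copula triggers are structural (dependency labels), so they
need no word list. The engine is deliberately semantic-free: solvent and
treatment contexts ("dichloromethane extract of Feverfew") are predicted
POS, and constructions outside the table ("tobacco-specific nitrosamines")
are predicted NEG — the model's documented error modes, which the packaged
fixtures reproduce.

Evaluation utilities cover precision/recall/F1
(F = 2PR/(P+R)), simple percent agreement
(agreements/(agreements+disagreements) × 100) and Cohen's kappa
((p_o − p_e)/(1 − p_e)).

## Worked example

```python
>>> from plantchem import classify_unit, default_triggers, worked_examples
>>> triggers = default_triggers()
>>> fig = next(f for f in worked_examples() if f.template_id == "V2")
>>> fig.unit.sentence.text
'About 450 mg of FB1 were obtained from 800 g cultured corn.'
>>> label, matches = classify_unit(fig.graph, fig.unit, triggers)
>>> label.value, matches[0].rule_id
('POS', 'V2')
>>> [fig.graph.tokens[i].text for i in matches[0].trigger_tokens]
['obtained', 'from']
```

The chemical FB1 sits in the passive subject NP ("About 450 mg of FB1"),
the plant in the prepositional object ("800 g cultured corn"), and the
root verb "obtained" is in the passive trigger list — the passive verbal
structure (V2), so the unit is positive.

From the shell, the same pipeline over a synthetic corpus:

```bash
$ plantchem generate --n 40 --seed 5 --out gen/
wrote 40 units to gen
$ plantchem classify --bioc gen/corpus.bioc.xml --parses gen/parses.conll \
      --out gen/pred.bioc.xml
classified 40 units (24 POS)
$ plantchem evaluate --gold gen/corpus.bioc.xml --pred gen/pred.bioc.xml
{
  "overall": {
    "tp": 20, "fp": 4, "fn": 0, "tn": 16,
    "precision": 83.3, "recall": 100.0, "f1": 90.9
  }
}
```

The four false positives are the generated confounder sentences (solvent
extracts and treatment contexts), which the syntactic model fires on by
design. Other subcommands: `convert` (BioC ↔ annotation sheet), `units`
(abstracts → candidate units), `extract` (full pipeline), `agreement`
(inter-annotator statistics).

## Corpus formats

Corpora travel as **BioC XML** (documents → sentence passages →
plant/chemical annotations → POS/NEG relations with weak/strong triggers)
or as a 15-column tab-separated **annotation sheet**
(`PlantName, P.ID, P.Off, …, Sentence, PMID, Label, WeakTrigger,
StrongTrigger`). Both round-trip losslessly. Dependency parses are
supplied as 4-column CoNLL-style files; any parser can be adapted, and a
Universal-Dependencies → Stanford label mapping is included.

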