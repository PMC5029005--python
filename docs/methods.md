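# Methods

## Task and data model

The package extracts sentence-level *containment* relationships between
plants and chemicals. The unit of annotation, prediction and evaluation is
the **corpus unit**: one (plant mention, chemical mention) pair inside one
sentence. A sentence with *p* plant and *c* chemical mentions yields
exactly *p·c* units; a unit is **POS** when the sentence states that the
plant contains, yields, synthesises or is partly composed of the chemical,
and **NEG** otherwise. Relations are deliberately not tracked across
sentence boundaries: restricting to single sentences keeps the syntactic
rule model well-defined and maximises the lexical diversity of plant names
per unit of annotation effort.

Entity mentions carry 0-based half-open character spans (sentence-relative
everywhere except BioC locations, which are document-relative, per BioC
convention) and database identifiers restricted by class: Taxonomy/TCMID
for plants, MeSH/CHEMBL/CAS for chemicals, with `NA` for unmapped names.
POS units carry a *weak trigger* (a token sequence, annotated as broadly as
possible) and a *strong trigger* (exactly one word); NEG units carry
neither — these invariants are enforced by validation at every I/O
boundary.

## Pipeline

1. **NER.** Dictionary exact matching: case-insensitive, token-boundary
   anchored, longest-match left-to-right without overlaps. Token
   boundaries are transitions to non-alphanumeric characters, so hyphens
   are boundaries ("tobacco" is found inside "tobacco-specific") and
   nothing matches inside a longer alphanumeric run. Matching is on
   surface forms, not lemmas. Cross-class overlaps (a span claimed by both
   lexicons) are resolved longer-span-first, with ties going to the plant;
   this resolution is not specified by the task and is a package
   convention, logged when applied. The chemical recognizer is a pluggable
   callable so a statistical chemical NER system can replace the
   dictionary.
2. **Sentence splitting.** Rule-based default: a `.`, `!` or `?` followed
   by whitespace and an uppercase letter or digit ends a sentence, guarded
   by an abbreviation list and a single-initial rule ("A. thaliana").
   The splitter is pluggable; spans are ordered, disjoint, and cover all
   non-whitespace text.
3. **Co-occurrence and expansion.** Keep exactly the sentences with at
   least one plant and one chemical mention; expand each into its
   Cartesian product of units, ordered by plant span then chemical span.
   Balancing positive/negative classes is a manual curation step in corpus
   construction; the package supplies only a seeded random sampler.

## The rule engine

Each unit is classified on a dependency parse in the Stanford basic
(uncollapsed) typed-dependency vocabulary. An entity is *inside* an NP
when its syntactic head token lies in the NP's subtree; a mention's head is
its right-most token whose governor lies outside the mention.

**Noun phrases.** NP(h) collects every descendant of a nominal head *h*
reachable without crossing `partmod`, `rcmod`, `ccomp`, `advcl`, `conj`,
`appos` or `punct`. Prepositional chains therefore stay inside the NP
("the volatile oil **of ginger**" keeps the plant), while participial and
relative clauses, conjuncts and apposed NPs do not. Excluding `appos`
keeps an apposed restatement out of its governor's NP — otherwise the
prepositional family would fire inside every apposition structure —
and excluding punctuation makes NP token distances count word tokens only.
For the attachment side of the prepositional rule, an entity's NP is
anchored at its *maximal nominal projection*: the head reached by climbing
`nn`/`amod`/`num`/`quantmod`/`poss` links (so "dichloromethane" in "the
dichloromethane extract" projects to "extract").

**Families**, evaluated in the fixed order V, P, R, A, C, CN (the order
decides only which match is reported first; the POS/NEG label is
order-independent):

* **Verbal.** V1: an active-list verb with an `nsubj` subtree containing
  the plant and a `dobj` subtree containing the chemical. V2: a
  passive-list verb with the chemical under `nsubjpass` and the plant under
  any `prep`+`pobj` chain. V3: "consist(s)" with the plant under `nsubj`
  and the chemical under `prep`+`pobj`.
* **Prepositional.** A `prep` edge attached inside one entity's NP whose
  `pobj` subtree contains the other entity (plant-first = P1, chemical-
  first = P2). Attachment anywhere in the NP subtree is accepted, which is
  what lets "Saponins **from** the flowers of Panax notoginseng" fire.
* **Relative.** R1: a passive-list participle modifying (`partmod`/`amod`)
  the chemical's NP head, with the plant under the participle's
  `prep`+`pobj`. R2: a gerund-list modifier of the plant's NP head with
  the chemical in its `dobj` subtree; the intransitive gerund "consisting"
  instead requires its object via the preposition "of".
* **Apposition.** Any `appos` edge with one entity on the governor side
  (excluding the apposed branch) and the other inside the apposed NP, with
  strictly fewer than `max_dist` tokens between the two NPs.
* **Copula.** Any `cop` edge — every tense of *be* — with one entity in
  the predicate's `nsubj` subtree and the other in the remainder of the
  predicate subtree, under the same distance bound.
* **Compound noun.** Exactly one whitespace between the plant mention's
  end and the chemical mention's start ("Aloe emodin"), plant first only.
  This rule is character-level and needs no parse.

**Parameters.** `max_dist` (default 10, CLI `--appos-max-dist`) bounds the
token distance for the apposition and copula families; the bound is strict
(< 10 intervening tokens), resolving the ambiguity between "within ten" and
"less than ten" in the rule statement toward the strict reading. Trigger
word lists (packaged, editable as a sectioned text file): 54 active forms
(18 verbs × 3 inflections), 29 passive/past-participle forms (one set
serving both the verbal and relative families), `consist`/`consists`, and
19 gerunds. Triggers are matched on lowercased surface tokens because the
lists enumerate inflected forms explicitly.

**Known error modes, preserved by design.** The engine has no semantics:
solvent extracts ("dichloromethane extract of Feverfew") and agronomic
treatments ("ammonia treatment of rice straw") fire the prepositional rule
and are false positives; "plant-specific chemical" compounds and
parenthesised sources ("3-(methylthio)propanal (cooked potato)") have no
rule structure and are false negatives. Negation, hedging and coordination
scope are not modelled. The packaged error fixtures assert these
behaviours rather than fixing them.

## Parses

No statistical parser is bundled. Parses arrive as 4-column CoNLL-style
files (index, form, head, deprel; `# text =` comments carry the exact
sentence string), produced either by the fixture/generator machinery or by
an external parser behind the adapter contract (sentence text in,
`DependencyGraph` out, Stanford labels). Adapters emitting Universal
Dependencies can use the packaged label mapping (`nsubj:pass→nsubjpass`,
`obj→dobj`, `compound→nn`, `acl→partmod`, `obl`/`nmod`→`pobj`,
`case→prep`); the `obl`/`nmod` arm is approximate, and emitting Stanford
labels directly is preferred. Basic (uncollapsed) dependencies are
assumed. Unknown labels are ignored by the rules and logged once per
label.

## Synthetic data

The generator emulates the *structural* conditions of the rule-development
corpus: one sentence template per rule structure (12 positive templates),
four trigger-free negative templates, and two confounder templates
mimicking the documented solvent-extract and treatment false positives.
Entity names are single-token surface forms from the worked examples'
vocabulary; each sentence carries a programmatically built gold parse
consistent with its template, so rule-engine tests are independent of any
parser. Class mix defaults to a balanced corpus (positive fraction 0.5,
matching the corpus design of roughly equal positives and negatives) with
a 0.1 confounder fraction; counts are allocated deterministically
(`round(n·fraction)`) and the order shuffled by the seed, so a fixed seed
reproduces a byte-identical corpus.

What passing on synthetic data does *not* show: robustness to parser
errors, multi-word or ambiguous entity names, lexical variety beyond the
template vocabulary, or the real corpus's class ratio. The worked-example
fixtures cover more realistic sentence structure but are still hand-parsed
gold trees, not parser output.

## Evaluation statistics

Precision, recall and F1 are computed from POS/NEG confusion counts and
reported as percentages with one-decimal half-up rounding (the table
convention; the rounding mode is a package choice). `prf_from_pr` exposes
the harmonic-mean identity F = 2PR/(P+R) directly on printed
precision/recall percentages. Simple percent agreement is
agreements/(agreements+disagreements) × 100. Cohen's kappa,
(p_o − p_e)/(1 − p_e), accepts any square label-by-label matrix (k > 2
categories included) and raises on the degenerate p_e = 1 case. Annotator
comparison reports unit-level label agreement; joint entity-and-relation
agreement is counted as unit-level conjunction (both label and both entity
spans equal), which is one of two defensible readings and is labelled as
such in the CLI output.

## Problem sizes and numerical choices

The test suite and acceptance script run on the 16 packaged worked-example
units, generated corpora of 20–200 units, and randomized property checks
(trees ≤ 15 tokens, 2×2 agreement tables) — sizes at which the brute-force
oracles are exact and the whole suite completes in seconds. Ties in the
dictionary matcher (same span reachable through different lexicon casings)
merge identifier sets; writer output is canonically ordered (documents by
pmid, annotations by span) so serialization is deterministic and
`write∘read` is idempotent byte-for-byte.

## Limitations

* The annotation sheet has no sentence-offset column, so a sentence's
  document offset does not survive a sheet round-trip (BioC preserves it).
* Abstract text is reconstructed from passages on BioC read; characters in
  inter-sentence gaps are normalised to spaces.
* The dictionary NER cannot recognise unseen names, acronyms, or formula
  variants; the recognizer slot exists precisely to plug in a stronger
  chemical tagger.
* V1 does not admit passive paraphrases of active triggers ("is contained
  by"); only the tabled structures are implemented.
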