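import random

import pytest

from plantchem.depgraph import DependencyGraph, Token
from plantchem.fixtures import worked_examples
from plantchem.lexicons import (
    default_triggers,
    fixture_chemical_lexicon,
    fixture_plant_lexicon,
)

_LABELS = [
    "nsubj", "dobj", "prep", "pobj", "nn", "amod", "det", "appos", "cop",
    "partmod", "rcmod", "conj", "cc", "advmod", "num", "punct", "ccomp",
]


@pytest.fixture(scope="session")
def triggers():
    return default_triggers()


@pytest.fixture(scope="session")
def plant_lex():
    return fixture_plant_lexicon()


@pytest.fixture(scope="session")
def chem_lex():
    return fixture_chemical_lexicon()


@pytest.fixture(scope="session")
def examples():
    """Worked-example fixtures keyed by template id."""
    return {f.template_id: f for f in worked_examples()}


def make_random_tree(rng: random.Random, n: int) -> DependencyGraph:
    """A random single-rooted dependency tree over n tokens.

    Token i > 0 attaches to a random earlier token, which guarantees a
    single root (token 0) and acyclicity by construction.
    """
    tokens = []
    pos = 0
    for i in range(n):
        text = f"w{i}"
        tokens.append(Token(i, text, pos, pos + len(text)))
        pos += len(text) + 1
    edges = [
        (rng.randrange(i), i, rng.choice(_LABELS)) for i in range(1, n)
    ]
    return DependencyGraph(tokens, edges, text=" ".join(t.text for t in tokens))
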