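"""Dependency-parse data model and the subtree/NP utilities the rules need.

Graphs use the Stanford typed-dependency label vocabulary (basic, uncollapsed:
``prep`` + ``pobj`` rather than ``prep_of``).  A graph is a single-rooted tree:
every non-root token has exactly one head.  Parses arrive either from the
packaged CoNLL-style fixture files (:func:`read_conll`) or from an external
parser adapter; adapters emitting Universal Dependencies labels can be mapped
onto the Stanford set with :func:`map_ud_labels`.

Noun-phrase extraction (:func:`np_subtree`) collects every descendant of a
nominal head reachable without crossing a clausal boundary, so prepositional
chains stay inside the NP ("the volatile oil of ginger" keeps "ginger") while
participial clauses, relative clauses and conjuncts do not.  Appositions and
punctuation are likewise excluded: an apposed NP is a restatement, not part of
the phrase, and punctuation never counts toward NP membership or the token
distances used by the apposition/copula constraints.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .errors import CorpusParseError, IntegrityError
from .model import EntityMention

logger = logging.getLogger(__name__)

__all__ = [
    "Token",
    "DependencyGraph",
    "NounPhrase",
    "read_conll",
    "write_conll",
    "map_ud_labels",
    "mention_head",
    "np_subtree",
    "nominal_head",
    "token_distance",
    "CLAUSAL_LABELS",
    "NP_BLOCKED_LABELS",
    "UD_TO_STANFORD",
]

#: Labels that terminate an NP: clausal modifiers and conjunction.
CLAUSAL_LABELS = frozenset({"partmod", "rcmod", "ccomp", "advcl", "conj"})

#: Full blacklist for NP membership: clausal labels plus apposition (an
#: apposed NP restates, it does not belong) and punctuation.
NP_BLOCKED_LABELS = CLAUSAL_LABELS | {"appos", "punct"}

#: Labels a token may climb through to find the head of its maximal nominal
#: projection ("calcium" in "the calcium contents" projects to "contents").
NOMINAL_CLIMB_LABELS = frozenset({"nn", "amod", "num", "quantmod", "poss"})

#: Universal Dependencies -> Stanford basic dependency label mapping for
#: parser adapters.  ``obl``/``nmod`` become ``prep``-chain objects only
#: approximately; adapters should prefer emitting Stanford labels directly.
UD_TO_STANFORD = {
    "nsubj:pass": "nsubjpass",
    "aux:pass": "auxpass",
    "obj": "dobj",
    "compound": "nn",
    "acl": "partmod",
    "acl:relcl": "rcmod",
    "obl": "pobj",
    "nmod": "pobj",
    "case": "prep",
    "nummod": "num",
    "nmod:poss": "poss",
    "det:predet": "det",
}

_KNOWN_LABELS = frozenset(
    {
        "root", "nsubj", "nsubjpass", "dobj", "iobj", "prep", "pobj", "appos",
        "cop", "nn", "amod", "det", "num", "quantmod", "poss", "partmod",
        "rcmod", "ccomp", "xcomp", "advcl", "advmod", "conj", "cc", "aux",
        "auxpass", "mark", "punct", "neg", "dep", "prt", "expl", "tmod",
        "npadvmod", "acomp", "pcomp", "predet", "preconj", "csubj",
        "csubjpass", "parataxis", "discourse", "vocative", "infmod",
    }
)
_warned_labels: set[str] = set()


@dataclass(frozen=True)
class Token:
    """A surface token with its 0-based position and character span."""

    index: int
    text: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class NounPhrase:
    """A noun phrase as a head token plus its member token indices."""

    head: int
    members: frozenset[int]

    def __post_init__(self) -> None:
        if self.head not in self.members:
            raise IntegrityError("NounPhrase head must be one of its members")


class DependencyGraph:
    """Tokens plus single-head typed-dependency edges (a rooted tree)."""

    def __init__(
        self,
        tokens: Sequence[Token],
        edges: Iterable[tuple[int, int, str]],
        text: str | None = None,
    ):
        self.tokens: tuple[Token, ...] = tuple(tokens)
        self.text = text
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise IntegrityError(f"token indices not contiguous at {i}")
        head: dict[int, tuple[int, str]] = {}
        children: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n)}
        for h, d, label in edges:
            if not (0 <= h < n and 0 <= d < n):
                raise IntegrityError(f"edge ({h}, {d}, {label}) out of range")
            if d in head:
                raise IntegrityError(f"token {d} has multiple heads")
            if label not in _KNOWN_LABELS and label not in _warned_labels:
                _warned_labels.add(label)
                logger.warning("unknown dependency label %r (ignored by rules)", label)
            head[d] = (h, label)
            children[h].append((d, label))
        roots = [i for i in range(n) if i not in head]
        if n and len(roots) != 1:
            raise IntegrityError(f"graph must have exactly one root, found {roots}")
        self.root: int = roots[0] if n else -1
        self._head = head
        self._children = {h: tuple(sorted(cs)) for h, cs in children.items()}
        # acyclicity: walking up from every token must reach the root
        for i in range(n):
            seen = set()
            j = i
            while j in head:
                if j in seen:
                    raise IntegrityError(f"dependency cycle through token {i}")
                seen.add(j)
                j = head[j][0]

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DependencyGraph):
            return NotImplemented
        return self.tokens == other.tokens and self._head == other._head

    def head_of(self, index: int) -> tuple[int, str] | None:
        """Return ``(head index, label)`` or None for the root."""
        return self._head.get(index)

    def children(self, index: int) -> tuple[tuple[int, str], ...]:
        return self._children.get(index, ())

    def children_with(self, index: int, label: str) -> tuple[int, ...]:
        return tuple(d for d, lab in self.children(index) if lab == label)

    def subtree(self, index: int) -> frozenset[int]:
        """All descendants of ``index``, inclusive."""
        out = {index}
        stack = [index]
        while stack:
            for d, _ in self.children(stack.pop()):
                if d not in out:
                    out.add(d)
                    stack.append(d)
        return frozenset(out)

    def edges(self) -> list[tuple[int, int, str]]:
        return sorted((h, d, lab) for d, (h, lab) in self._head.items())

    def edges_with(self, label: str) -> list[tuple[int, int]]:
        return [(h, d) for h, d, lab in self.edges() if lab == label]

    def token_text(self, index: int, lower: bool = True) -> str:
        t = self.tokens[index].text
        return t.lower() if lower else t


def np_subtree(graph: DependencyGraph, head: int) -> NounPhrase:
    """The noun phrase headed at ``head``.

    Descendants are collected without traversing any label in
    :data:`NP_BLOCKED_LABELS`, so nominal modifiers and prep/pobj chains stay
    in while clauses, conjuncts, appositions and punctuation stay out.
    """
    members = {head}
    stack = [head]
    while stack:
        for d, label in graph.children(stack.pop()):
            if label in NP_BLOCKED_LABELS or d in members:
                continue
            members.add(d)
            stack.append(d)
    return NounPhrase(head=head, members=frozenset(members))


def nominal_head(graph: DependencyGraph, index: int) -> int:
    """Head token of the maximal nominal projection containing ``index``.

    Climbs head links while the incoming label is a nominal modifier
    (``nn``/``amod``/``num``/``quantmod``/``poss``), so "dichloromethane" in
    "the dichloromethane extract" projects to "extract".
    """
    i = index
    while True:
        up = graph.head_of(i)
        if up is None or up[1] not in NOMINAL_CLIMB_LABELS:
            return i
        i = up[0]


def token_distance(np_a: NounPhrase, np_b: NounPhrase) -> int:
    """Number of tokens strictly between the closest members of two NPs."""
    if np_a.members & np_b.members:
        raise IntegrityError("token_distance requires disjoint noun phrases")
    return min(abs(a - b) for a in np_a.members for b in np_b.members) - 1


def mention_head(graph: DependencyGraph, mention: EntityMention) -> int:
    """The syntactic head token of a mention.

    Returns the mention token whose head lies outside the mention span (the
    right-most such token when the parse offers several), mirroring the
    head-final convention of English noun compounds.
    """
    overlapping = [
        t.index
        for t in graph.tokens
        if t.start < mention.end and t.end > mention.start
    ]
    if not overlapping:
        raise IntegrityError(
            f"mention {mention.text!r} [{mention.start}, {mention.end}) "
            "overlaps no token of the parse"
        )
    inside = set(overlapping)
    heads = [
        i
        for i in overlapping
        if graph.head_of(i) is None or graph.head_of(i)[0] not in inside
    ]
    return max(heads) if heads else max(overlapping)


# ---------------------------------------------------------------------------
# CoNLL-style fixture I/O (4 columns: index, form, head, deprel; 1-based
# indices with head 0 = root, blocks separated by blank lines, optional
# "# text = ..." comment giving the exact sentence string).
# ---------------------------------------------------------------------------


def _assign_spans(text: str, forms: Sequence[str]) -> list[Token]:
    tokens = []
    cursor = 0
    for i, form in enumerate(forms):
        pos = text.find(form, cursor)
        if pos < 0:
            raise CorpusParseError(
                f"token {form!r} not found in sentence text after offset {cursor}"
            )
        tokens.append(Token(i, form, pos, pos + len(form)))
        cursor = pos + len(form)
    return tokens


def graph_from_rows(
    rows: Sequence[tuple[str, int, str]], text: str | None = None
) -> tuple[str, DependencyGraph]:
    """Build a graph from (form, 1-based head, deprel) rows."""
    forms = [form for form, _, _ in rows]
    sent_text = text if text is not None else " ".join(forms)
    tokens = _assign_spans(sent_text, forms)
    edges = [
        (h - 1, d, label)
        for d, (_, h, label) in enumerate(rows)
        if h != 0
    ]
    return sent_text, DependencyGraph(tokens, edges, text=sent_text)


def read_conll(source: str | Path | TextIO) -> list[tuple[str, DependencyGraph]]:
    """Read dependency fixtures; returns ``(sentence_text, graph)`` pairs."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_conll(fh)
    out: list[tuple[str, DependencyGraph]] = []
    rows: list[tuple[str, int, str]] = []
    text: str | None = None
    row_numbers: list[int] = []

    def flush() -> None:
        nonlocal rows, text
        if rows:
            try:
                out.append(graph_from_rows(rows, text))
            except IntegrityError as exc:
                raise IntegrityError(
                    f"{exc} (sentence ending at line {row_numbers[-1]})"
                ) from exc
        rows, text = [], None
        row_numbers.clear()

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            if line.startswith("# text ="):
                text = line.split("=", 1)[1].strip()
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise CorpusParseError(f"line {lineno}: expected 4 columns, got {fields!r}")
        idx, form, head, deprel = fields[0], fields[1], fields[2], fields[3]
        try:
            idx_i, head_i = int(idx), int(head)
        except ValueError as exc:
            raise CorpusParseError(f"line {lineno}: non-integer index/head") from exc
        if idx_i != len(rows) + 1:
            raise CorpusParseError(
                f"line {lineno}: expected token index {len(rows) + 1}, got {idx_i}"
            )
        rows.append((form, head_i, deprel))
        row_numbers.append(lineno)
    flush()
    return out


def write_conll(
    parses: Iterable[tuple[str, DependencyGraph]], target: str | Path | TextIO
) -> None:
    """Serialize ``(sentence_text, graph)`` pairs in the fixture format."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            write_conll(parses, fh)
            return
    for text, graph in parses:
        target.write(f"# text = {text}\n")
        for tok in graph.tokens:
            up = graph.head_of(tok.index)
            head = 0 if up is None else up[0] + 1
            label = "root" if up is None else up[1]
            target.write(f"{tok.index + 1}\t{tok.text}\t{head}\t{label}\n")
        target.write("\n")


def conll_string(parses: Iterable[tuple[str, DependencyGraph]]) -> str:
    buf = io.StringIO()
    write_conll(parses, buf)
    return buf.getvalue()


def map_ud_labels(graph: DependencyGraph) -> DependencyGraph:
    """Translate Universal Dependencies labels to the Stanford dialect."""
    edges = [
        (h, d, UD_TO_STANFORD.get(label, label)) for h, d, label in graph.edges()
    ]
    return DependencyGraph(graph.tokens, edges, text=graph.text)
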