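import io
import random

import pytest

from plantchem.depgraph import (
    NP_BLOCKED_LABELS,
    DependencyGraph,
    NounPhrase,
    Token,
    conll_string,
    map_ud_labels,
    mention_head,
    np_subtree,
    read_conll,
    token_distance,
    write_conll,
)
from plantchem.errors import CorpusParseError, IntegrityError
from plantchem.model import EntityClass, EntityMention

from conftest import make_random_tree


def find_token(graph, text):
    return next(t.index for t in graph.tokens if t.text == text)


def mention_for(graph, surface):
    start = graph.text.find(surface)
    return EntityMention(
        entity_class=EntityClass.PLANT,
        start=start,
        end=start + len(surface),
        text=surface,
    )


# --- oracles (independent brute-force implementations) ---------------------


def oracle_subtree(graph, head):
    changed = True
    members = {head}
    while changed:
        changed = False
        for i in range(len(graph)):
            up = graph.head_of(i)
            if up and up[0] in members and i not in members:
                members.add(i)
                changed = True
    return members


def oracle_np(graph, head):
    members = {head}
    frontier = [head]
    while frontier:
        nxt = []
        for i in range(len(graph)):
            up = graph.head_of(i)
            if (
                up
                and up[0] in frontier
                and up[1] not in NP_BLOCKED_LABELS
                and i not in members
            ):
                members.add(i)
                nxt.append(i)
        frontier = nxt
    return members


def oracle_mention_head(graph, mention):
    overlap = [
        t.index
        for t in graph.tokens
        if t.start < mention.end and t.end > mention.start
    ]
    external = [
        i
        for i in overlap
        if graph.head_of(i) is None or graph.head_of(i)[0] not in overlap
    ]
    return max(external) if external else max(overlap)


# --- CoNLL I/O --------------------------------------------------------------


class TestConll:
    def test_packaged_passive_example_has_root_obtained(self, examples):
        graph = examples["V2"].graph
        assert graph.tokens[graph.root].text == "obtained"
        head, label = graph.head_of(find_token(graph, "mg"))
        assert (graph.tokens[head].text, label) == ("obtained", "nsubjpass")

    def test_one_token_sentence_is_root_only(self):
        parses = read_conll(io.StringIO("1\tHello\t0\troot\n"))
        [(text, graph)] = parses
        assert text == "Hello" and graph.root == 0 and len(graph) == 1

    def test_random_trees_roundtrip(self):
        rng = random.Random(0)
        parses = [
            (" ".join(f"w{i}" for i in range(n)), make_random_tree(rng, n))
            for n in range(1, 12)
        ]
        again = read_conll(io.StringIO(conll_string(parses)))
        assert [g for _, g in again] == [g for _, g in parses]
        assert [t for t, _ in again] == [t for t, _ in parses]

    def test_multi_head_reports_row(self):
        bad = "1\ta\t0\troot\n2\tb\t1\tnn\n2\tb\t1\tnn\n"
        with pytest.raises(CorpusParseError, match="expected token index"):
            read_conll(io.StringIO(bad))
        bad = "1\ta\t2\tnn\n2\tb\t1\tnn\n"
        with pytest.raises(IntegrityError, match="line 2"):
            read_conll(io.StringIO(bad))

    def test_ud_labels_map_to_stanford(self):
        rows = "1\tFB1\t2\tnsubj:pass\n2\tobtained\t0\troot\n3\tcorn\t2\tobl\n"
        [(_, graph)] = read_conll(io.StringIO(rows))
        mapped = map_ud_labels(graph)
        assert mapped.head_of(0)[1] == "nsubjpass"
        assert mapped.head_of(2)[1] == "pobj"


# --- mention_head -----------------------------------------------------------


class TestMentionHead:
    def test_multiword_mention_head_is_compound_head(self, examples):
        graph = examples["V1"].graph
        m = mention_for(graph, "Punica granatum")
        assert graph.tokens[mention_head(graph, m)].text == "granatum"

    def test_single_token_mention(self, examples):
        graph = examples["V1"].graph
        m = mention_for(graph, "anthocyanins")
        assert graph.tokens[mention_head(graph, m)].text == "anthocyanins"

    def test_no_overlap_raises(self, examples):
        graph = examples["V1"].graph
        m = EntityMention(EntityClass.PLANT, 0, 3, "Pom")
        far = EntityMention(EntityClass.PLANT, 1000, 1003, "xyz")
        assert mention_head(graph, m) == 0
        with pytest.raises(IntegrityError):
            mention_head(graph, far)

    def test_equals_bruteforce_on_random_trees(self):
        rng = random.Random(1)
        for _ in range(80):
            graph = make_random_tree(rng, rng.randint(2, 12))
            a = rng.randrange(len(graph))
            b = rng.randrange(a, len(graph))
            m = EntityMention(
                EntityClass.PLANT,
                graph.tokens[a].start,
                graph.tokens[b].end,
                graph.text[graph.tokens[a].start : graph.tokens[b].end],
            )
            assert mention_head(graph, m) == oracle_mention_head(graph, m)


# --- np_subtree / token_distance -------------------------------------------


class TestNounPhrase:
    def test_passive_subject_np_keeps_prepositional_chain(self, examples):
        graph = examples["V2"].graph
        np = np_subtree(graph, find_token(graph, "mg"))
        assert find_token(graph, "FB1") in np.members

    def test_leaf_head_is_singleton(self, examples):
        graph = examples["V2"].graph
        leaf = find_token(graph, "FB1")
        assert np_subtree(graph, leaf).members == {leaf}

    def test_equals_bruteforce_on_random_trees(self):
        rng = random.Random(2)
        for _ in range(120):
            graph = make_random_tree(rng, rng.randint(1, 15))
            head = rng.randrange(len(graph))
            assert np_subtree(graph, head).members == oracle_np(graph, head)
            assert graph.subtree(head) == oracle_subtree(graph, head)

    def test_apposition_distance_counts_only_the_comma(self, examples):
        # "[soybean oil], [a source of unsaturated fatty acids]"
        graph = examples["A1"].graph
        oil = find_token(graph, "oil")
        source = find_token(graph, "source")
        np_a = NounPhrase(oil, frozenset({find_token(graph, "soybean"), oil}))
        np_b = np_subtree(graph, source)
        assert token_distance(np_a, np_b) == 1

    def test_adjacent_nps_have_distance_zero(self):
        a = NounPhrase(0, frozenset({0, 1}))
        b = NounPhrase(2, frozenset({2, 3}))
        assert token_distance(a, b) == 0

    def test_distance_is_symmetric(self):
        rng = random.Random(5)
        for _ in range(50):
            cut = rng.randint(1, 8)
            a = NounPhrase(0, frozenset(range(cut)))
            lo = cut + rng.randint(0, 4)
            b = NounPhrase(lo, frozenset(range(lo, lo + rng.randint(1, 4))))
            assert token_distance(a, b) == token_distance(b, a)

    def test_overlapping_nps_rejected(self):
        a = NounPhrase(0, frozenset({0, 1, 2}))
        b = NounPhrase(2, frozenset({2, 3}))
        with pytest.raises(IntegrityError):
            token_distance(a, b)


class TestGraphInvariants:
    def test_double_root_rejected(self):
        tokens = [Token(0, "a", 0, 1), Token(1, "b", 2, 3)]
        with pytest.raises(IntegrityError, match="exactly one root"):
            DependencyGraph(tokens, [])

    def test_cycle_rejected(self):
        tokens = [Token(0, "a", 0, 1), Token(1, "b", 2, 3), Token(2, "c", 4, 5)]
        with pytest.raises(IntegrityError):
            DependencyGraph(tokens, [(1, 2, "nn"), (2, 1, "nn")])

    def test_conll_writer_output_is_stable(self, tmp_path):
        rng = random.Random(3)
        parses = [("w0 w1 w2", make_random_tree(rng, 3))]
        p1, p2 = tmp_path / "a.conll", tmp_path / "b.conll"
        write_conll(parses, p1)
        write_conll(parses, p2)
        assert p1.read_text() == p2.read_text()
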