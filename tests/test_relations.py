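"""Parse loading, path extraction, distant supervision, pattern learning."""

import random

import pytest

from litmine.bioc import BioCDocument, BioCPassage, BioCSentence
from litmine.relations import (AlignmentError, CandidatePair,
                               DegeneratePathError, DependencyNode,
                               DependencyTree, ParseTableError, PathSignature,
                               PatternTable, candidate_pairs, distant_label,
                               entity_head, extract_path, learn_patterns,
                               load_parses, read_conll, score_syntax)
from test_disambiguation import _ann

# The coimmunoprecipitation sentence: Tim18p subject of the verb, Tim12p
# attached as prepositional object.
COIP_TEXT = "Tim18p coimmunoprecipitated with Tim12p ."
COIP_CONLL = """1\tTim18p\ttim18p\tNN\t2\tsubj
2\tcoimmunoprecipitated\tcoimmunoprecipitate\tVBD\t0\troot
3\twith\twith\tIN\t2\tmodpp
4\tTim12p\ttim12p\tNN\t2\tpobj
5\t.\t.\t.\t2\tpunct
"""


def _doc(sentences):
    doc = BioCDocument(id="d1")
    passage = BioCPassage(offset=0)
    pos = 0
    for i, text in enumerate(sentences):
        passage.sentences.append(BioCSentence(offset=pos, text=text, index=i))
        pos += len(text) + 1
    doc.passages.append(passage)
    return doc


def _tree(conll):
    return DependencyTree(sentence_index=0, nodes=read_conll(conll)[0])


# ---------------------------------------------------------------------------
# parse loading

def test_load_parses_aligns_tokens_to_document_offsets():
    doc = _doc([COIP_TEXT, "It was specific ."])
    conll = COIP_CONLL + "\n" + (
        "1\tIt\tit\tPRP\t3\tsubj\n2\twas\tbe\tVBD\t3\taux\n"
        "3\tspecific\tspecific\tJJ\t0\troot\n4\t.\t.\t.\t3\tpunct\n")
    trees = load_parses(conll, doc)
    assert len(trees) == 2
    assert trees[0].alignment[1] == (0, 6)       # Tim18p
    assert trees[0].alignment[4] == (33, 6)      # Tim12p
    assert trees[1].alignment[1] == (42, 2)      # It, next sentence


def test_two_roots_rejected():
    bad = COIP_CONLL.replace("2\tcoimmunoprecipitated\tcoimmunoprecipitate\tVBD\t0",
                             "2\tcoimmunoprecipitated\tcoimmunoprecipitate\tVBD\t0"
                             ).replace("3\twith\twith\tIN\t2", "3\twith\twith\tIN\t0")
    with pytest.raises(ParseTableError, match="roots"):
        load_parses(bad, _doc([COIP_TEXT]))


def test_cyclic_heads_rejected():
    bad = ("1\ta\ta\tNN\t2\tsubj\n2\tb\tb\tNN\t1\tobj\n")
    with pytest.raises(ParseTableError, match="cyclic|roots"):
        load_parses(bad, _doc(["a b"]))


def test_block_count_mismatch_is_alignment_error():
    with pytest.raises(AlignmentError, match="blocks"):
        load_parses(COIP_CONLL, _doc([COIP_TEXT, "Another sentence ."]))


def test_unlocatable_token_is_alignment_error():
    with pytest.raises(AlignmentError, match="not found"):
        load_parses(COIP_CONLL, _doc(["Completely different text here okay ."]))


# ---------------------------------------------------------------------------
# path extraction

def test_coip_sentence_yields_subj_pobj_path():
    tree = _tree(COIP_CONLL)
    sig = extract_path(tree, 1, 4)
    assert sig == PathSignature("coimmunoprecipitate", ("subj",), ("pobj",))


def test_entity_at_lca_has_empty_path():
    # chain a <- b <- c: entity heads at a and its governor b
    conll = "1\ta\ta\tNN\t2\tmod\n2\tb\tb\tNN\t3\tmod\n3\tc\tc\tNN\t0\troot\n"
    sig = extract_path(_tree(conll), 1, 2)
    assert sig == PathSignature("b", ("mod",), ())


def test_chain_tree_lca_at_top():
    conll = "1\ta\ta\tNN\t2\tl1\n2\tb\tb\tNN\t3\tl2\n3\tc\tc\tNN\t0\troot\n"
    sig = extract_path(_tree(conll), 1, 3)
    assert sig == PathSignature("c", ("l2", "l1"), ())


def test_identical_heads_degenerate():
    with pytest.raises(DegeneratePathError):
        extract_path(_tree(COIP_CONLL), 2, 2)


def test_path_symmetric_under_entity_swap():
    tree = _tree(COIP_CONLL)
    fwd = extract_path(tree, 1, 4)
    rev = extract_path(tree, 4, 1)
    assert (fwd.top_lemma, fwd.left_path, fwd.right_path) == \
        (rev.top_lemma, rev.right_path, rev.left_path)


def test_multitoken_entity_head_is_syntactic_head():
    doc = _doc(["Homo sapiens cells grow ."])
    conll = ("1\tHomo\thomo\tNN\t2\tnn\n2\tsapiens\tsapiens\tNN\t3\tnn\n"
             "3\tcells\tcell\tNNS\t4\tsubj\n4\tgrow\tgrow\tVB\t0\troot\n"
             "5\t.\t.\t.\t4\tpunct\n")
    tree = load_parses(conll, doc)[0]
    ann = _ann("Homo sapiens", 0, "species", "taxon:9606", sentence=0)
    assert entity_head(tree, ann) == 2  # sapiens: its head lies outside the span


def brute_force_path(tree, a, b):
    """Oracle: ancestor-set intersection; deepest common ancestor is the LCA."""
    def ancestors(n):
        out = []
        while n != 0:
            out.append(n)
            n = tree.node(n).head
        return out
    anc_a, anc_b = ancestors(a), ancestors(b)
    common = set(anc_a) & set(anc_b)
    lca = max(common, key=lambda n: len(ancestors(n)))
    left = [tree.node(n).label for n in anc_a[: anc_a.index(lca)]][::-1]
    right = [tree.node(n).label for n in anc_b[: anc_b.index(lca)]][::-1]
    return PathSignature(tree.node(lca).lemma, tuple(left), tuple(right))


def random_tree(rng, n):
    nodes = []
    for i in range(1, n + 1):
        head = 0 if i == 1 else rng.randrange(1, i)
        nodes.append(DependencyNode(i, f"w{i}", f"l{i}", "NN", head,
                                    rng.choice("abcde")))
    return DependencyTree(sentence_index=0, nodes=nodes)


def test_lca_agrees_with_ancestor_set_oracle(rng):
    for _ in range(300):
        n = rng.randrange(2, 12)
        tree = random_tree(rng, n)
        a, b = rng.sample(range(1, n + 1), 2)
        assert extract_path(tree, a, b) == brute_force_path(tree, a, b)


# ---------------------------------------------------------------------------
# candidates

def _protein_sentence_annotations():
    return [_ann("P1s", 0, "protein", "P1", sentence=0),
            _ann("P2s", 10, "protein", "P2", sentence=0),
            _ann("P3s", 20, "protein", "P3", sentence=0)]


def test_three_proteins_give_three_pairs():
    pairs = candidate_pairs(_protein_sentence_annotations(),
                            [("protein", "protein")], "d1")
    assert len(pairs) == 3
    assert all(p.a.offset < p.b.offset for p in pairs)


def test_chemical_disease_pair():
    anns = [_ann("aspirin", 0, "chemical", "C1", sentence=0),
            _ann("headache", 10, "disease", "D1", sentence=0)]
    assert len(candidate_pairs(anns, [("chemical", "disease")], "d1")) == 1
    assert candidate_pairs(anns, [("protein", "protein")], "d1") == []


def test_same_concept_pair_suppressed():
    anns = [_ann("cdc2", 0, "protein", "P1", sentence=0),
            _ann("Cdc2", 10, "protein", "P1", sentence=0)]
    assert candidate_pairs(anns, [("protein", "protein")], "d1") == []
    assert len(candidate_pairs(anns, [("protein", "protein")], "d1",
                               allow_self=True)) == 1


def test_pairs_only_within_sentences():
    anns = [_ann("P1s", 0, "protein", "P1", sentence=0),
            _ann("P2s", 50, "protein", "P2", sentence=1)]
    assert candidate_pairs(anns, [("protein", "protein")], "d1") == []


# ---------------------------------------------------------------------------
# distant supervision

GOLD = {("d1", "P1", "P2")}


def test_sentence_with_gold_pair_positive():
    doc = _doc(["x", "y"])
    anns = [_ann("a", 0, "protein", "P1", sentence=0),
            _ann("b", 1, "protein", "P2", sentence=0)]
    labels = distant_label(doc, anns, GOLD)
    assert labels == {0: "positive", 1: "negative"}


def test_non_gold_pair_negative():
    doc = _doc(["x"])
    anns = [_ann("a", 0, "protein", "P1", sentence=0),
            _ann("c", 1, "protein", "P3", sentence=0)]
    assert distant_label(doc, anns, GOLD)[0] == "negative"


def test_single_mention_negative():
    doc = _doc(["x"])
    anns = [_ann("a", 0, "protein", "P1", sentence=0)]
    assert distant_label(doc, anns, GOLD)[0] == "negative"


# ---------------------------------------------------------------------------
# pattern learning and scoring

def _coip_corpus_item():
    doc = _doc([COIP_TEXT])
    anns = [_ann("Tim18p", 0, "protein", "P1", sentence=0),
            _ann("Tim12p", 33, "protein", "P2", sentence=0)]
    trees = load_parses(COIP_CONLL, doc)
    return doc, anns, trees


def test_single_positive_sentence_learns_yes_pattern():
    table = learn_patterns([_coip_corpus_item()], GOLD)
    sig = PathSignature("coimmunoprecipitate", ("subj",), ("pobj",))
    assert table.counts[sig] == [1, 0]
    assert table.decision(sig) == "yes"


def test_minority_positive_ratio_decides_no():
    table = PatternTable(theta=0.5)
    sig = PathSignature("x", ("a",), ("b",))
    table.add(sig, True)
    for _ in range(3):
        table.add(sig, False)
    assert table.ratio(sig) == 0.25
    assert table.decision(sig) == "no"


def test_empty_corpus_empty_table():
    assert len(learn_patterns([], GOLD)) == 0


def test_counts_permutation_invariant():
    items = [_coip_corpus_item() for _ in range(3)]
    fwd = learn_patterns(items, GOLD)
    rev = learn_patterns(items[::-1], GOLD)
    assert fwd.counts == rev.counts


def test_sentence_mode_uses_sentence_labels():
    doc, anns, trees = _coip_corpus_item()
    # P1-P3 is not gold, but the sentence also holding the gold P1-P2 pair
    # is positive, so in sentence mode the non-gold pair counts positive too
    anns.append(_ann("with", 28, "protein", "P3", sentence=0))
    table_pair = learn_patterns([(doc, anns, trees)], GOLD, mode="pair")
    table_sent = learn_patterns([(doc, anns, trees)], GOLD, mode="sentence")
    pos_pair = sum(c[0] for c in table_pair.counts.values())
    pos_sent = sum(c[0] for c in table_sent.counts.values())
    assert pos_pair == 1 and pos_sent == 3


def test_score_syntax_yes_pattern_is_ratio():
    doc, anns, trees = _coip_corpus_item()
    sig = PathSignature("coimmunoprecipitate", ("subj",), ("pobj",))
    table = PatternTable()
    table.counts[sig] = [3, 1]
    cand = CandidatePair("d1", 0, anns[0], anns[1])
    score_syntax(cand, trees[0], table)
    assert cand.syntactic_score == 0.75
    assert cand.pattern == sig


def test_score_syntax_no_pattern_is_zero():
    doc, anns, trees = _coip_corpus_item()
    sig = PathSignature("coimmunoprecipitate", ("subj",), ("pobj",))
    table = PatternTable()
    table.counts[sig] = [0, 5]
    cand = CandidatePair("d1", 0, anns[0], anns[1])
    score_syntax(cand, trees[0], table)
    assert cand.syntactic_score == 0.0


def test_unseen_path_backs_off():
    doc, anns, trees = _coip_corpus_item()
    cand = CandidatePair("d1", 0, anns[0], anns[1])
    score_syntax(cand, trees[0], PatternTable(), backoff=0.25)
    assert cand.syntactic_score == 0.25


def test_unparsed_sentence_leaves_score_absent():
    doc, anns, _ = _coip_corpus_item()
    cand = CandidatePair("d1", 0, anns[0], anns[1])
    score_syntax(cand, None, PatternTable())
    assert cand.syntactic_score is None


def test_pattern_table_tsv_round_trip():
    table = learn_patterns([_coip_corpus_item()], GOLD)
    again = PatternTable.from_tsv(table.to_tsv())
    assert again.counts == table.counts
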