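"""Tokenizer, surface normalization, lexicon loading, dictionary matcher."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from litmine.terminology import (Lexicon, LexiconEntry, LexiconLoadError,
                                 annotate, load_lexicon, match_tokens,
                                 normalize_surface, tokenize)
from conftest import make_passage


# ---------------------------------------------------------------------------
# tokenize

def test_tokenize_word_offsets_counted_in_characters():
    toks = tokenize("Tim18p coimmunoprecipitated with Tim12p")
    assert [(t.text, t.offset) for t in toks] == [
        ("Tim18p", 0), ("coimmunoprecipitated", 7), ("with", 28), ("Tim12p", 33)]


def test_tokenize_empty_input():
    assert tokenize("") == []


def test_tokenize_splits_hyphens_and_keeps_punctuation():
    toks = tokenize("IL-2-dependent")
    assert [t.text for t in toks] == ["IL", "-", "2", "-", "dependent"]
    # reconstruction: token texts at their offsets reproduce the input
    buf = [" "] * len("IL-2-dependent")
    for t in toks:
        buf[t.offset : t.end] = t.text
    assert "".join(buf) == "IL-2-dependent"


def test_tokenize_respects_base_offset():
    toks = tokenize("ab cd", base_offset=100)
    assert [t.offset for t in toks] == [100, 103]


# ---------------------------------------------------------------------------
# normalize_surface

@pytest.mark.parametrize("surface,expected", [
    ("IL-2", "il2"),
    ("Il 2", "il2"),
    ("alpha-synuclein", "alphasynuclein"),
    ("α-synuclein", "alphasynuclein"),
    ("Heat shock proteins", "heatshockprotein"),
    ("TGF-β", "tgfbeta"),
    ("kinases", "kinase"),
    ("class", "class"),      # 'ss' guard keeps stripping idempotent
    ("sex", "sex"),          # too short for plural stripping
])
def test_normalize_variants_unify(surface, expected):
    assert normalize_surface(surface) == expected


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(st.text(max_size=30))
def test_normalize_is_idempotent(s):
    once = normalize_surface(s)
    assert normalize_surface(once) == once


# ---------------------------------------------------------------------------
# load_lexicon

LEX_TSV = (
    "surface\tconcept_id\tentity_type\tpreferred_name\tsource_db\torganism_id\n"
    "Tim18p\tP1\tprotein\tTIM18\tPROTDB\ttaxon:4932\n"
    "aspirin\tC1\tchemical\taspirin\tCHEMDB\t\n"
    "acetylsalicylic acid\tC1\tchemical\taspirin\tCHEMDB\t\n"
)


def test_load_lexicon_counts_and_index():
    lex = load_lexicon(LEX_TSV)
    assert len(lex) == 3
    assert len(lex.index) >= 2
    assert lex.types_available == {"protein", "chemical"}


def test_load_lexicon_missing_column_errors_by_name():
    with pytest.raises(LexiconLoadError, match="entity_type"):
        load_lexicon("surface\tconcept_id\tpreferred_name\tsource_db\nx\t1\tn\tdb\n")


def test_short_and_common_word_surfaces_flagged_case_sensitive():
    lex = load_lexicon(
        "surface\tconcept_id\tentity_type\tpreferred_name\tsource_db\n"
        "folD\tG1\tgene\tfolD\tGENEDB\n"
        "SEX\tC2\tchemical\tsodium ethyl xanthate\tCHEMDB\n"
        "staurosporine\tC3\tchemical\tstaurosporine\tCHEMDB\n")
    flags = {e.surface: e.case_sensitive for e in lex.entries}
    assert flags == {"folD": True, "SEX": True, "staurosporine": False}


def test_same_surface_two_concepts_shares_one_key():
    lex = load_lexicon(
        "surface\tconcept_id\tentity_type\tpreferred_name\tsource_db\n"
        "Cdc2\tP_yeast\tprotein\tCDC2\tPROTDB\n"
        "Cdc2\tP_human\tprotein\tCDK1\tPROTDB\n")
    entries = lex.lookup(normalize_surface("Cdc2"))
    assert {e.concept_id for e in entries} == {"P_yeast", "P_human"}


def test_duplicate_rows_collapse():
    lex = load_lexicon(LEX_TSV + "Tim18p\tP1\tprotein\tTIM18\tPROTDB\ttaxon:4932\n")
    assert len(lex) == 3


# ---------------------------------------------------------------------------
# annotate

def test_annotate_simple_lookup(tiny_lexicon):
    passage = make_passage("Tim18p binds Tim12p")
    anns = annotate(passage, tiny_lexicon)
    assert [(a.offset, a.length, a.infons["concept_id"]) for a in anns] == [
        (0, 6, "P1"), (13, 6, "P2")]
    assert all(a.text == "Tim18p binds Tim12p"[a.offset:a.end] for a in anns)


def test_annotate_matches_surface_variants(tiny_lexicon):
    passage = make_passage("IL 2 and α-synuclein were detected")
    anns = annotate(passage, tiny_lexicon)
    assert {a.infons["concept_id"] for a in anns} == {"P3", "P4"}
    il2 = next(a for a in anns if a.infons["concept_id"] == "P3")
    assert il2.text == "IL 2"


def test_annotate_preserves_common_word_match_for_downstream_filter(tiny_lexicon):
    # the matcher itself is case-blind; the disambiguation stage drops "fold"
    anns = annotate(make_passage("the fold of the protein"), tiny_lexicon)
    assert [a.infons["concept_id"] for a in anns] == ["G1"]
    assert anns[0].infons["case_sensitive"] == "true"


def test_annotate_empty_lexicon_gives_empty_result():
    assert annotate(make_passage("anything at all"), Lexicon([])) == []


def test_annotate_type_restriction_equals_posthoc_filter(tiny_lexicon):
    passage = make_passage("aspirin treats headache says Tim18p")
    restricted = annotate(passage, tiny_lexicon, requested_types={"chemical"})
    full = annotate(passage, tiny_lexicon)
    expected = [(a.offset, a.length, a.infons["concept_id"]) for a in full
                if a.infons["type"] == "chemical"]
    assert [(a.offset, a.length, a.infons["concept_id"]) for a in restricted] == expected


def test_annotate_does_not_cross_sentence_boundaries():
    lex = Lexicon([LexiconEntry("heat shock", "X1", "process", "hs", "DB")])
    passage = make_passage(None, sentences=["we applied heat", "shock followed"])
    assert annotate(passage, lex) == []
    joined = make_passage("we applied heat shock followed")
    assert len(annotate(joined, lex)) == 1


def test_longest_match_wins_and_suppresses_nested():
    lex = Lexicon([
        LexiconEntry("heat shock protein", "X1", "protein", "HSP", "DB"),
        LexiconEntry("shock", "X2", "process", "shock", "DB"),
    ])
    anns = annotate(make_passage("the heat shock protein family"), lex)
    assert [a.infons["concept_id"] for a in anns] == ["X1"]


# ---------------------------------------------------------------------------
# matcher vs brute-force window oracle

def brute_force_matches(tokens, text, base, lexicon, max_span=8):
    """Independent oracle: enumerate every window, then apply the greedy
    longest-match left-to-right policy over the enumerated hits."""
    hits = {}
    for i in range(len(tokens)):
        for w in range(1, min(max_span, len(tokens) - i) + 1):
            span = text[tokens[i].offset - base : tokens[i + w - 1].end - base]
            entries = lexicon.lookup(normalize_surface(span))
            if entries:
                hits.setdefault(i, []).append((w, entries))
    chosen = []
    i = 0
    while i < len(tokens):
        if i in hits:
            w, entries = max(hits[i], key=lambda x: x[0])
            chosen.append((i, w, entries))
            i += w
        else:
            i += 1
    return chosen


def random_document_and_lexicon(rng):
    vocab = [f"{c}{v}{n}" for c in "bcdfg" for v in "aeiou" for n in range(3)]
    surfaces = rng.sample(vocab, 12)
    multi = [f"{rng.choice(surfaces)} {rng.choice(surfaces)}" for _ in range(3)]
    entries = []
    for i, s in enumerate(surfaces[:8] + multi):
        entries.append(LexiconEntry(s, f"X{i}", rng.choice(["protein", "chemical"]),
                                    s, "DB"))
    lex = Lexicon(entries)
    words = surfaces + ["the", "of", "with", "binds", "-", "cells"]
    text = " ".join(rng.choice(words) for _ in range(rng.randrange(5, 30)))
    return text.replace(" - ", "-"), lex


@pytest.mark.parametrize("seed", [0, 1])
def test_matcher_equals_brute_force_oracle(seed):
    rng = random.Random(seed)
    for _ in range(100):
        text, lex = random_document_and_lexicon(rng)
        tokens = tokenize(text)
        got = match_tokens(tokens, text, 0, lex)
        expected = brute_force_matches(tokens, text, 0, lex)
        def norm(ms):
            return [(i, w, sorted(e.concept_id for e in ee)) for i, w, ee in ms]
        assert norm(got) == norm(expected)
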