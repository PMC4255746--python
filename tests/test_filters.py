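"""Sentence-filter grammar, evaluation, and the truth-table oracle."""

import random

import pytest

from litmine.bioc import BioCDocument, BioCPassage, BioCSentence
from litmine.filters import (And, Atom, FilterSyntaxError, Not, Or,
                             apply_filter, parse_filter)
from test_disambiguation import _ann

TYPES = ["protein", "chemical", "disease"]


def _doc(sentence_anns):
    """Build a document whose sentence i carries the given annotation types."""
    doc = BioCDocument(id="d1")
    passage = BioCPassage(offset=0)
    pos = 0
    for i, types in enumerate(sentence_anns):
        text = f"sentence number {i} with {len(types)} things ."
        sent = BioCSentence(offset=pos, text=text, index=i)
        for j, t in enumerate(types):
            sent.annotations.append(
                _ann(f"e{i}{j}", pos + j, t, f"{t[:2].upper()}{j}", sentence=i))
        passage.sentences.append(sent)
        pos += len(text) + 1
    doc.passages.append(passage)
    return doc


# ---------------------------------------------------------------------------
# parsing

def test_conjunction_parses():
    expr = parse_filter("has_type(chemical) AND has_type(disease)")
    assert isinstance(expr, And)
    assert expr.left == Atom("has_type", ("chemical",))


def test_precedence_not_and_or():
    expr = parse_filter("NOT has_term(gfp) OR has_type(gene)")
    assert isinstance(expr, Or)
    assert isinstance(expr.left, Not)


def test_keywords_case_insensitive_and_parens():
    expr = parse_filter("has_type(a) and (has_type(b) or not has_type(c))")
    assert isinstance(expr, And)
    assert isinstance(expr.right, Or)


def test_syntax_error_reports_column():
    with pytest.raises(FilterSyntaxError) as err:
        parse_filter("has_type(")
    assert err.value.column >= 9


def test_unknown_type_rejected():
    with pytest.raises(FilterSyntaxError, match="unknown entity type"):
        parse_filter("has_type(martian)", known_types={"protein"})


def test_printer_round_trips():
    for text in ["has_type(chemical) AND has_type(disease)",
                 "NOT has_term(gfp) OR has_type(gene)",
                 "(has_type(a) OR has_type(b)) AND NOT has_concept(C1)",
                 "has_relation(chemical, disease)"]:
        expr = parse_filter(text)
        assert parse_filter(str(expr)) == expr


# ---------------------------------------------------------------------------
# evaluation

def test_type_conjunction_selects_mixed_sentences():
    doc = _doc([["protein"], ["chemical", "disease"], ["chemical"],
                ["chemical", "disease"], [], ["disease"]] + [["protein"]] * 4)
    selected, ratio = apply_filter(
        doc, parse_filter("has_type(chemical) AND has_type(disease)"))
    assert selected == [1, 3]
    assert 0 < ratio < 1


def test_negation_on_uniform_document_selects_nothing():
    doc = _doc([["protein"]] * 5)
    selected, ratio = apply_filter(doc, parse_filter("NOT has_type(protein)"))
    assert selected == [] and ratio == 0.0


def test_has_relation_needs_two_distinct_annotations():
    doc = _doc([["protein"], ["protein", "protein"]])
    selected, _ = apply_filter(doc, parse_filter("has_relation(protein, protein)"))
    assert selected == [1]


def test_selection_and_complement_partition_sentences():
    doc = _doc([["protein"], ["chemical"], [], ["disease", "chemical"]])
    for text in ["has_type(chemical)", "has_type(protein) OR has_type(disease)"]:
        expr = parse_filter(text)
        pos, _ = apply_filter(doc, expr)
        neg, _ = apply_filter(doc, Not(expr))
        assert sorted(pos + neg) == [0, 1, 2, 3]
        assert not set(pos) & set(neg)


def test_or_grows_and_never_shrinks_selection():
    doc = _doc([[t] for t in TYPES] + [["chemical", "disease"]])
    base = parse_filter("has_type(chemical)")
    wider = Or(base, parse_filter("has_type(disease)"))
    narrower = And(base, parse_filter("has_type(disease)"))
    s_base, _ = apply_filter(doc, base)
    s_wide, _ = apply_filter(doc, wider)
    s_narrow, _ = apply_filter(doc, narrower)
    assert set(s_base) <= set(s_wide)
    assert set(s_narrow) <= set(s_base)


# ---------------------------------------------------------------------------
# random filters vs truth-table oracle

def random_expr(rng, depth=0):
    if depth > 3 or rng.random() < 0.4:
        kind = rng.choice(["has_type", "has_concept", "has_relation"])
        if kind == "has_type":
            return Atom("has_type", (rng.choice(TYPES),))
        if kind == "has_concept":
            t = rng.choice(TYPES)
            return Atom("has_concept", (f"{t[:2].upper()}{rng.randrange(3)}",))
        return Atom("has_relation", (rng.choice(TYPES), rng.choice(TYPES)))
    op = rng.choice(["and", "or", "not"])
    if op == "not":
        return Not(random_expr(rng, depth + 1))
    cls = And if op == "and" else Or
    return cls(random_expr(rng, depth + 1), random_expr(rng, depth + 1))


def oracle_eval(expr, anns):
    """Independent evaluator: compute atom truth values by direct scans,
    then evaluate the printed boolean formula."""
    atoms = {}

    def collect(e):
        if isinstance(e, Atom):
            atoms.setdefault(e, None)
        elif isinstance(e, Not):
            collect(e.operand)
        else:
            collect(e.left)
            collect(e.right)

    collect(expr)
    for atom in atoms:
        if atom.name == "has_type":
            atoms[atom] = any(a.infons["type"] == atom.args[0] for a in anns)
        elif atom.name == "has_concept":
            atoms[atom] = any(a.infons["concept_id"] == atom.args[0] for a in anns)
        elif atom.name == "has_relation":
            t1, t2 = atom.args
            counts = {}
            for a in anns:
                counts[a.infons["type"]] = counts.get(a.infons["type"], 0) + 1
            atoms[atom] = (counts.get(t1, 0) >= 2 if t1 == t2
                           else counts.get(t1, 0) >= 1 and counts.get(t2, 0) >= 1)

    def ev(e):
        if isinstance(e, Atom):
            return atoms[e]
        if isinstance(e, Not):
            return not ev(e.operand)
        if isinstance(e, And):
            return ev(e.left) and ev(e.right)
        return ev(e.left) or ev(e.right)

    return ev(expr)


def test_filter_engine_matches_truth_table_oracle(rng):
    for _ in range(100):
        doc = _doc([[rng.choice(TYPES) for _ in range(rng.randrange(0, 4))]
                    for _ in range(rng.randrange(1, 8))])
        expr = random_expr(rng)
        selected, _ = apply_filter(doc, expr)
        expected = [s.index for s in doc.sentences()
                    if oracle_eval(expr, s.annotations)]
        assert selected == expected


def test_sparse_relations_yield_strong_reduction(standard_bundle):
    """Chemical-disease triage: the filter keeps every planted
    chemical+disease sentence while discarding most of the text."""
    from litmine.pipeline import PipelineConfig, process_collection
    result = process_collection(standard_bundle.collection,
                                standard_bundle.lexicon,
                                PipelineConfig(type_rules=standard_bundle.type_rules))
    expr = parse_filter("has_type(chemical) AND has_type(disease)")
    total_kept = total_chars = 0
    kept_indices = {}
    for doc in result.collection.documents:
        selected, _ = apply_filter(doc, expr)
        kept_indices[doc.id] = set(selected)
        for s in doc.sentences():
            total_chars += len(s.text)
            if s.index in kept_indices[doc.id]:
                total_kept += len(s.text)
    planted = {(d, i) for (d, i), tpl in standard_bundle.sentence_templates.items()
               if tpl == "chemdis"}
    assert planted  # the fixture really planted some
    assert all(i in kept_indices[d] for d, i in planted)
    assert total_kept / total_chars < 0.5
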