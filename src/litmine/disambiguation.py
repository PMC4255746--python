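"""Resolution of the three ambiguity classes of dictionary-matched terms.

1. *Common-word collisions* — a technical term that is also an ordinary
   word (a gene called folD, a chemical called SEX).  Matches of
   case-sensitive lexicon entries survive only when the document spells
   the term exactly as the lexicon does.
2. *Cross-type conflicts* — the same surface belongs to two entity types
   (GFP: a protein, but usually mentioned as part of a fluorescence
   microscopy readout).  Simple context rules (cue lemmas in a token
   window) pick the type; with no firing rule all candidates are kept and
   flagged ambiguous.
3. *Multiple identifiers within one type* — the same gene/protein name in
   many species.  A ranked list of focus organisms is computed from the
   document (species mentions plus genes resolvable to a single
   organism); identifiers from non-focus organisms are pruned, with a
   fail-safe that never empties a candidate list (the recognizer aims at
   high recall).

The canonical pipeline order is common-word filter -> type resolution ->
organism ranking -> identifier pruning; the sequence is idempotent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .bioc import BioCAnnotation, BioCDocument, BioCPassage
from .terminology import Lexicon, normalize_surface, tokenize

__all__ = [
    "OrganismScore",
    "RuleConfigError",
    "TypeContextRule",
    "apply_common_word_filter",
    "disambiguate_document",
    "disambiguate_ids",
    "load_type_rules",
    "rank_organisms",
    "resolve_type_conflicts",
]

DEFAULT_GAMMA = 0.5  # weight of uniquely-resolving gene/protein mentions
ORGANISM_SCOPED_TYPES = frozenset({"gene", "protein"})

_CANDIDATE_SEP = ";"
_CANDIDATE_FIELD_SEP = "|"


class RuleConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TypeContextRule:
    term_pattern: str       # normalized key the rule applies to
    preferred_type: str
    trigger_context: frozenset  # cue lemmas (normalized)
    window: int = 6         # tokens on each side of the mention


@dataclass(frozen=True)
class OrganismScore:
    organism_id: str
    score: float


def load_type_rules(source: Union[str, io.IOBase],
                    known_types: Optional[set] = None) -> list:
    """Load context rules from TSV: pattern, preferred_type, cues (comma-sep), window."""
    if isinstance(source, str) and ("\t" in source or "\n" in source):
        fh = io.StringIO(source)
    elif isinstance(source, str):
        fh = open(source, encoding="utf-8")
    else:
        fh = source
    rules = []
    with fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pattern, preferred, cues, window = line.split("\t")
            if known_types is not None and preferred not in known_types:
                raise RuleConfigError(
                    f"type rule for {pattern!r} prefers unknown type {preferred!r}"
                )
            rules.append(TypeContextRule(
                term_pattern=normalize_surface(pattern),
                preferred_type=preferred,
                trigger_context=frozenset(
                    normalize_surface(c) for c in cues.split(",") if c.strip()
                ),
                window=int(window),
            ))
    return rules


# ---------------------------------------------------------------------------
# 1. common-word collisions

def apply_common_word_filter(annotations: Iterable, lexicon: Lexicon = None) -> list:
    """Drop matches of case-sensitive entries whose document surface differs.

    A case-sensitive lexicon entry (short symbol or common-word collision)
    is kept only when the text spells it exactly as the lexicon does;
    every other annotation passes through unchanged.
    """
    kept = []
    for ann in annotations:
        if ann.infons.get("case_sensitive") == "true":
            if ann.text != ann.infons.get("lexicon_surface"):
                continue
        kept.append(ann)
    return kept


# ---------------------------------------------------------------------------
# 2. cross-type conflicts

def _context_window_tokens(ann: BioCAnnotation, passage: BioCPassage, window: int) -> set:
    """Normalized tokens within `window` tokens on either side of the mention."""
    unit = None
    for s in passage.sentences:
        if s.offset <= ann.offset and ann.end <= s.end:
            unit = (s.text, s.offset)
            break
    if unit is None:
        unit = (passage.effective_text, passage.offset)
    tokens = tokenize(unit[0], unit[1])
    inside = [i for i, t in enumerate(tokens)
              if t.offset >= ann.offset and t.end <= ann.end]
    if inside:
        lo, hi = inside[0], inside[-1]
    else:  # mention not on token boundaries; fall back to positional search
        lo = hi = next((i for i, t in enumerate(tokens) if t.end > ann.offset), 0)
    ctx = tokens[max(0, lo - window) : lo] + tokens[hi + 1 : hi + 1 + window]
    return {normalize_surface(t.text) for t in ctx}


def resolve_type_conflicts(annotations: Sequence, rules: Sequence,
                           passage: BioCPassage) -> list:
    """Resolve spans annotated with several entity types.

    If a rule matches the span's normalized surface and one of its cue
    lemmas occurs within the token window, only the preferred type
    survives; otherwise all types are kept and flagged
    ``ambiguous_type=true``.  Unconflicted annotations pass through.
    """
    by_span: dict = {}
    for ann in annotations:
        by_span.setdefault(ann.span(), []).append(ann)
    resolved = []
    for span_anns in by_span.values():
        types = {a.infons["type"] for a in span_anns}
        if len(types) == 1:
            resolved.extend(span_anns)
            continue
        key = normalize_surface(span_anns[0].text)
        winner = None
        for rule in rules:
            if rule.term_pattern != key or rule.preferred_type not in types:
                continue
            ctx = _context_window_tokens(span_anns[0], passage, rule.window)
            if ctx & rule.trigger_context:
                winner = rule.preferred_type
                break
        for ann in span_anns:
            if winner is None:
                ann.infons["ambiguous_type"] = "true"
                resolved.append(ann)
            elif ann.infons["type"] == winner:
                ann.infons.pop("ambiguous_type", None)
                resolved.append(ann)
    resolved.sort(key=lambda a: (a.offset, a.length, a.infons["type"], a.infons["concept_id"]))
    return resolved


# ---------------------------------------------------------------------------
# 3. organism ranking and identifier pruning

def _candidate_groups(annotations: Iterable) -> dict:
    """Group annotations by (span, type); each group is one mention."""
    groups: dict = {}
    for ann in annotations:
        groups.setdefault((ann.span(), ann.infons["type"]), []).append(ann)
    return groups


def _unpack(packed: str) -> list:
    return [tuple(item.split(_CANDIDATE_FIELD_SEP))
            for item in packed.split(_CANDIDATE_SEP) if item]


def _candidates_of(ann: BioCAnnotation) -> list:
    """(concept_id, organism_id, preferred_name) candidates carried by one annotation.

    A previously disambiguated annotation records its complete original
    candidate set in ``all_candidate_ids``; using that set (rather than
    the pruned survivors) keeps the pipeline idempotent under re-runs.
    """
    full = ann.infons.get("all_candidate_ids", "")
    if full:
        return _unpack(full)
    cands = [(ann.infons["concept_id"], ann.infons.get("organism_id") or "",
              ann.infons.get("preferred_name", ""))]
    cands.extend(_unpack(ann.infons.get("candidate_ids", "")))
    return cands


def rank_organisms(annotations: Iterable, gamma: float = DEFAULT_GAMMA) -> list:
    """Rank the document's focus organisms.

    score(o) = #species mentions of o + gamma * #gene/protein mentions whose
    candidate identifier set is compatible with o only, normalized to sum
    to 1.  Ties break by taxonomy identifier ascending; no evidence at all
    yields an empty list.
    """
    raw: dict = {}
    for (span, etype), group in sorted(_candidate_groups(annotations).items()):
        if etype == "species":
            org = group[0].infons.get("organism_id") or group[0].infons["concept_id"]
            raw[org] = raw.get(org, 0.0) + 1.0
        elif etype in ORGANISM_SCOPED_TYPES:
            orgs = {org for ann in group for _, org, _ in _candidates_of(ann) if org}
            if len(orgs) == 1:
                org = next(iter(orgs))
                raw[org] = raw.get(org, 0.0) + gamma
    total = sum(raw.values())
    if total <= 0:
        return []
    ranked = sorted(raw.items(), key=lambda kv: (-kv[1], kv[0]))
    return [OrganismScore(org, score / total) for org, score in ranked]


def disambiguate_ids(annotations: Iterable, organisms: Sequence) -> list:
    """Prune and rank multi-identifier gene/protein mentions by focus organism.

    Each (span, type) group collapses into a single annotation: candidates
    whose organism is not in the ranked focus list are removed, survivors
    sort by their organism's score descending (concept id as tie-break),
    the best candidate becomes ``concept_id`` and the rest ride in the
    ``candidate_ids`` infon.  If pruning would remove every candidate the
    unpruned list is kept (scored 0 for absent organisms) — the fail-safe
    that favors recall.  Organism-independent types (chemicals, diseases,
    ...) are merged and sorted by concept id but never pruned.
    """
    org_score = {o.organism_id: o.score for o in organisms}
    merged = []
    for (span, etype), group in sorted(_candidate_groups(annotations).items()):
        cands = []
        seen = set()
        for ann in group:
            for cand in _candidates_of(ann):
                if cand[0] not in seen:
                    seen.add(cand[0])
                    cands.append(cand)
        original = list(cands)
        if etype in ORGANISM_SCOPED_TYPES and org_score:
            pruned = [c for c in cands if c[1] in org_score]
            if pruned:
                cands = pruned
            cands.sort(key=lambda c: (-org_score.get(c[1], 0.0), c[0]))
        else:
            cands.sort(key=lambda c: c[0])
        head = group[0]
        if len(original) > 1:  # remembered so a re-run prunes from the same set
            head.infons["all_candidate_ids"] = _CANDIDATE_SEP.join(
                _CANDIDATE_FIELD_SEP.join(c) for c in sorted(original)
            )
        top = cands[0]
        head.infons["concept_id"] = top[0]
        if top[1]:
            head.infons["organism_id"] = top[1]
        else:
            head.infons.pop("organism_id", None)
        if top[2]:
            head.infons["preferred_name"] = top[2]
        rest = cands[1:]
        if rest:
            head.infons["candidate_ids"] = _CANDIDATE_SEP.join(
                _CANDIDATE_FIELD_SEP.join(c) for c in rest
            )
        else:
            head.infons.pop("candidate_ids", None)
        merged.append(head)
    merged.sort(key=lambda a: (a.offset, a.length, a.infons["type"], a.infons["concept_id"]))
    return merged


# ---------------------------------------------------------------------------
# full per-document pipeline

def disambiguate_document(doc: BioCDocument, annotations_by_passage: dict,
                          rules: Sequence = (), lexicon: Lexicon = None,
                          gamma: float = DEFAULT_GAMMA) -> dict:
    """Run the full disambiguation sequence on one document.

    ``annotations_by_passage`` maps passage index -> raw annotation list
    from :func:`litmine.terminology.annotate`.  Returns the same mapping
    with filtered, type-resolved, organism-pruned annotations.  The
    sequence (common-word filter -> type resolution -> organism ranking ->
    identifier pruning) is idempotent.
    """
    staged: dict = {}
    for p_idx, anns in annotations_by_passage.items():
        passage = doc.passages[p_idx]
        anns = apply_common_word_filter(anns, lexicon)
        anns = resolve_type_conflicts(anns, rules, passage)
        staged[p_idx] = anns
    all_anns = [a for anns in staged.values() for a in anns]
    organisms = rank_organisms(all_anns, gamma=gamma)
    return {p_idx: disambiguate_ids(anns, organisms) for p_idx, anns in staged.items()}
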