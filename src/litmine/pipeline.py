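"""End-to-end orchestration: annotate -> disambiguate -> relate -> rank.

One code path serves both the CLI and the REST service: a collection goes
in, an enriched copy comes out with scored entity annotations attached to
its sentences/passages and ranked interaction relations attached to its
passages, plus ranked candidate lists for export.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dataclass_field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from . import disambiguation, ranking, relations, terminology
from .bioc import BioCCollection, BioCDocument, BioCRelation, segment_passage
from .ranking import ConfidenceFactors, RankedCandidate
from .relations import CandidatePair, DependencyTree, PatternTable
from .terminology import Lexicon, normalize_surface

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "load_collection_parses",
    "process_collection",
]


@dataclass
class PipelineConfig:
    entity_types: Optional[Set[str]] = None          # None = all lexicon types
    relation_pairs: Set[frozenset] = dataclass_field(default_factory=set)
    type_rules: Sequence = ()
    gamma: float = disambiguation.DEFAULT_GAMMA      # organism-ranking gene weight
    theta: float = relations.DEFAULT_THETA           # pattern yes-decision threshold
    backoff: float = relations.DEFAULT_BACKOFF       # unseen-path prior
    max_span: int = terminology.DEFAULT_MAX_SPAN
    term_weights: Tuple[float, float, float] = ranking.DEFAULT_TERM_WEIGHTS
    interaction_weights: Tuple[float, float, float] = ranking.DEFAULT_INTERACTION_WEIGHTS
    bg_freq: Dict[str, float] = dataclass_field(default_factory=dict)
    concept_weight: Dict[str, float] = dataclass_field(default_factory=dict)
    allow_self_pairs: bool = False


@dataclass
class PipelineResult:
    collection: BioCCollection
    ranked_terms: Dict[str, list]          # document id -> RankedCandidate list
    ranked_interactions: List[RankedCandidate]  # global, rank-ordered
    candidates: List[CandidatePair]


def load_collection_parses(source, collection: BioCCollection) -> Dict[str, list]:
    """Split one CoNLL stream into per-document tree lists, by sentence order."""
    blocks = relations.read_conll(source)
    result: Dict[str, list] = {}
    cursor = 0
    for doc in collection.documents:
        n = sum(1 for _ in doc.sentences())
        result[doc.id] = relations.load_parses(blocks[cursor : cursor + n], doc)
        cursor += n
    if cursor != len(blocks):
        raise relations.AlignmentError(
            f"{len(blocks)} parse blocks for {cursor} sentences in collection"
        )
    return result


def _term_factors(doc_annotations: Sequence, config: PipelineConfig) -> Dict[int, ConfidenceFactors]:
    """Confidence factors per annotation (keyed by list position)."""
    total = len(doc_annotations)
    concept_mentions: Dict[str, int] = {}
    for ann in doc_annotations:
        cid = ann.infons["concept_id"]
        concept_mentions[cid] = concept_mentions.get(cid, 0) + 1
    out = {}
    for i, ann in enumerate(doc_annotations):
        key = normalize_surface(ann.infons.get("lexicon_surface", ann.text))
        out[i] = ConfidenceFactors(
            rel_freq=concept_mentions[ann.infons["concept_id"]] / total if total else 0.0,
            bg_freq=config.bg_freq.get(key, 0.0),
            context_factor=0.5 if ann.infons.get("ambiguous_type") == "true" else 1.0,
            concept_weight=config.concept_weight.get(ann.infons["concept_id"], 1.0),
        )
    return out


def _attach_annotations(doc: BioCDocument, by_passage: Dict[int, list]) -> None:
    counter = sum(1 for _ in doc.annotations())
    for p_idx, anns in sorted(by_passage.items()):
        passage = doc.passages[p_idx]
        for ann in anns:
            counter += 1
            ann.id = f"{doc.id}.T{counter}"
            target = passage
            for s in passage.sentences:
                if s.offset <= ann.offset and ann.end <= s.end:
                    target = s
                    break
            target.annotations.append(ann)


def process_collection(collection: BioCCollection, lexicon: Lexicon,
                       config: Optional[PipelineConfig] = None,
                       parses: Optional[Dict[str, list]] = None,
                       patterns: Optional[PatternTable] = None,
                       gold_db: Optional[set] = None) -> PipelineResult:
    """Run the full pipeline over a collection (the input is not mutated).

    Entity recognition and disambiguation always run; interaction
    extraction runs for the type pairs in ``config.relation_pairs``,
    syntax-scored when ``parses`` and ``patterns`` are supplied.  Output
    annotations carry ``score`` infons; relations carry ``score`` and
    ``rank`` and reference their argument annotations (roles arg1/arg2).
    Deterministic: identical inputs yield identical results.
    """
    config = config or PipelineConfig()
    coll = copy.deepcopy(collection)
    all_candidates: List[CandidatePair] = []
    ranked_terms: Dict[str, list] = {}
    interaction_items = []

    for doc in coll.documents:
        for p in doc.passages:
            segment_passage(p)   # input segmentation is preserved when present
        doc.reindex_sentences()
        raw = {
            i: terminology.annotate(p, lexicon, config.entity_types, config.max_span)
            for i, p in enumerate(doc.passages)
        }
        resolved = disambiguation.disambiguate_document(
            doc, raw, rules=config.type_rules, lexicon=lexicon, gamma=config.gamma
        )
        _attach_annotations(doc, resolved)
        doc_anns = [a for anns in resolved.values() for a in anns]
        factors = _term_factors(doc_anns, config)
        term_conf: Dict[str, float] = {}
        term_items = []
        for i, ann in enumerate(doc_anns):
            score = ranking.term_confidence(factors[i], config.term_weights)
            ann.infons["score"] = f"{score:.6f}"
            term_conf[ann.id] = score
            term_items.append((ann, factors[i], score))
        ranked_terms[doc.id] = ranking.rank(term_items)

        if not config.relation_pairs:
            continue
        cands = relations.candidate_pairs(
            doc_anns, config.relation_pairs, doc.id, config.allow_self_pairs
        )
        doc_trees = {t.sentence_index: t for t in (parses or {}).get(doc.id, [])}
        for cand in cands:
            if patterns is not None:
                relations.score_syntax(
                    cand, doc_trees.get(cand.sentence_index), patterns, config.backoff
                )
            fa = factors[doc_anns.index(cand.a)]
            fb = factors[doc_anns.index(cand.b)]
            fa.syntactic_factor = fb.syntactic_factor = cand.syntactic_score
            score = ranking.interaction_confidence(
                term_conf[cand.a.id], term_conf[cand.b.id], cand.syntactic_score,
                config.concept_weight.get(cand.a.infons["concept_id"], 1.0),
                config.concept_weight.get(cand.b.infons["concept_id"], 1.0),
                config.interaction_weights, config.backoff,
            )
            interaction_items.append((cand, (fa, fb), score))
        all_candidates.extend(cands)

    ranked_interactions = ranking.rank(interaction_items)
    _attach_relations(coll, ranked_interactions)
    return PipelineResult(coll, ranked_terms, ranked_interactions, all_candidates)


def _attach_relations(coll: BioCCollection, ranked: Sequence) -> None:
    docs = {d.id: d for d in coll.documents}
    counters = {d.id: sum(1 for _ in d.relations()) for d in coll.documents}
    for r in ranked:
        cand = r.payload
        doc = docs[cand.document_id]
        counters[doc.id] += 1
        rel = BioCRelation(
            id=f"{doc.id}.R{counters[doc.id]}",
            infons={
                "type": "interaction",
                "score": f"{r.score:.6f}",
                "rank": str(r.rank),
            },
            nodes=[(cand.a.id, "arg1"), (cand.b.id, "arg2")],
        )
        # relation lives in the passage holding its first argument
        for p in doc.passages:
            if p.offset <= cand.a.offset and cand.a.end <= p.end:
                p.relations.append(rel)
                break
        else:
            doc.passages[0].relations.append(rel)
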