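"""Confidence scoring and ranked output for assisted curation.

A curator should see the most trustworthy candidates first.  Confidence
combines, as a weighted product (log-linear form — monotone in every
factor and closed over [0,1]):

* the term's relative frequency in the document,
* its background corpus frequency (penalizing ubiquitous terms),
* a context factor reflecting unresolved type ambiguity,
* the syntactic-pattern factor for interactions, and
* a per-concept prior learned from the target database (how often the
  concept participates in a curated relation vs. merely co-occurring).

Ranked candidates carry a curation state (confirm / reject / undecided)
and export to CSV.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Union

from .relations import CandidatePair

__all__ = [
    "ConfidenceFactors",
    "RankedCandidate",
    "concept_weights",
    "export_csv",
    "interaction_confidence",
    "rank",
    "term_confidence",
]

DEFAULT_TERM_WEIGHTS = (1.0, 1.0, 1.0)       # rel_freq, 1-bg_freq, context
DEFAULT_INTERACTION_WEIGHTS = (1.0, 1.0, 1.0)  # term pair, syntax, concept prior
DEFAULT_BACKOFF = 0.25

CURATION_STATES = ("unset", "confirmed", "rejected", "undecided")


@dataclass
class ConfidenceFactors:
    rel_freq: float = 0.0
    bg_freq: float = 0.0
    context_factor: float = 1.0
    syntactic_factor: Optional[float] = None
    concept_weight: float = 1.0

    def validate(self) -> None:
        pairs = [("rel_freq", self.rel_freq), ("bg_freq", self.bg_freq),
                 ("context_factor", self.context_factor),
                 ("concept_weight", self.concept_weight)]
        if self.syntactic_factor is not None:
            pairs.append(("syntactic_factor", self.syntactic_factor))
        for name, value in pairs:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"confidence factor {name}={value} outside [0,1]")


@dataclass
class RankedCandidate:
    payload: object          # BioCAnnotation or CandidatePair
    factors: object          # ConfidenceFactors or (factors_a, factors_b)
    score: float
    rank: int = 0
    curation_state: str = "unset"


def concept_weights(gold_db: set, candidates: Iterable) -> Dict[str, float]:
    """Per-concept prior from the target database.

    weight(c) = (1 + #gold relations involving c) / (1 + #candidate pairs
    involving c), clipped to (0, 1]; a concept never seen in a candidate
    gets weight 1 (no penalty).  Concepts that co-occur often but are
    rarely curated — the noisy ones a high-recall recognizer drags in —
    are pushed down.
    """
    gold_count: Dict[str, int] = {}
    for _doc, a, b in gold_db:
        for c in (a, b):
            gold_count[c] = gold_count.get(c, 0) + 1
    cand_count: Dict[str, int] = {}
    for pair in candidates:
        for c in (pair.a.infons["concept_id"], pair.b.infons["concept_id"]):
            cand_count[c] = cand_count.get(c, 0) + 1
    weights = {}
    for c, n in cand_count.items():
        w = (1 + gold_count.get(c, 0)) / (1 + n)
        weights[c] = min(1.0, max(w, 1e-12))
    return weights


def term_confidence(factors: ConfidenceFactors,
                    weights: Sequence = DEFAULT_TERM_WEIGHTS) -> float:
    """Weighted product over relative frequency, background rarity, context."""
    factors.validate()
    w1, w2, w3 = weights
    return (factors.rel_freq ** w1) * ((1.0 - factors.bg_freq) ** w2) \
        * (factors.context_factor ** w3)


def interaction_confidence(term_conf_a: float, term_conf_b: float,
                           syntactic_factor: Optional[float],
                           concept_weight_a: float = 1.0,
                           concept_weight_b: float = 1.0,
                           weights: Sequence = DEFAULT_INTERACTION_WEIGHTS,
                           backoff: float = DEFAULT_BACKOFF) -> float:
    """Combine both participants' term confidences with syntax and priors.

    score = (t_a * t_b)^w_t * syntax^w_s * (c_a * c_b)^w_c; an absent
    syntactic factor (unparsed sentence) backs off to ``backoff``.
    Monotone non-decreasing in every factor.
    """
    syn = backoff if syntactic_factor is None else syntactic_factor
    w_t, w_s, w_c = weights
    return ((term_conf_a * term_conf_b) ** w_t) * (syn ** w_s) \
        * ((concept_weight_a * concept_weight_b) ** w_c)


def _first_offset(payload) -> int:
    if isinstance(payload, CandidatePair):
        return min(payload.a.offset, payload.b.offset)
    return payload.offset


def _concept_key(payload) -> str:
    if isinstance(payload, CandidatePair):
        return "|".join(sorted((payload.a.infons["concept_id"],
                                payload.b.infons["concept_id"])))
    return payload.infons["concept_id"]


def rank(scored: Iterable) -> list:
    """Order (payload, factors, score) triples or RankedCandidates.

    Stable sort, score descending; ties break by first mention offset
    ascending then concept id lexicographic.  Ranks are dense 1-based;
    curation state starts ``unset``.
    """
    items = []
    for item in scored:
        if isinstance(item, RankedCandidate):
            items.append(item)
        else:
            payload, factors, score = item
            items.append(RankedCandidate(payload, factors, score))
    items.sort(key=lambda r: (-r.score, _first_offset(r.payload), _concept_key(r.payload)))
    for i, r in enumerate(items, start=1):
        r.rank = i
    return items


def export_csv(ranked: Sequence, stream: Optional[io.TextIOBase] = None) -> str:
    """Write ranked candidates as CSV (the standard curation export)."""
    out = stream or io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(["rank", "score", "types", "concept_ids", "preferred_names",
                     "sentence_index", "curation_state"])
    for r in ranked:
        p = r.payload
        if isinstance(p, CandidatePair):
            types = ";".join([p.a.infons["type"], p.b.infons["type"]])
            ids = ";".join([p.a.infons["concept_id"], p.b.infons["concept_id"]])
            names = ";".join([p.a.infons.get("preferred_name", ""),
                              p.b.infons.get("preferred_name", "")])
            sent = str(p.sentence_index)
        else:
            types = p.infons["type"]
            ids = p.infons["concept_id"]
            names = p.infons.get("preferred_name", "")
            sent = p.infons.get("sentence_index", "")
        writer.writerow([r.rank, f"{r.score:.6g}", types, ids, names, sent,
                         r.curation_state])
    return out.getvalue() if stream is None else ""
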