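"""Candidate interaction generation and dependency-path pattern scoring.

Candidate interactions arise by simple co-occurrence of two entities in
one sentence; precision comes from the dependency tree connecting them.
For each pair we extract the syntactic path signature: the lemma of the
lowest common ancestor (LCA) of the two entity head tokens plus the two
downward edge-label sequences from the LCA to each head (e.g. top node
"coimmunoprecipitate", left path [subj], right path [pobj]).

Patterns are learned by distant supervision: a curated interaction
database projected onto the corpus labels each co-occurring pair (or each
sentence) positive/negative without hand annotation, and every observed
path accumulates yes/no counts.  At scoring time an exact path hit
returns the pattern's positive ratio (0 for a "no" pattern); unseen paths
back off to a configurable prior.

The dependency parser itself is out of scope: parses are consumed from a
6-column CoNLL-style table (index, surface, lemma, pos, head, label;
blank-line sentence separation) or from any callable producing the same
structures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .bioc import BioCAnnotation, BioCDocument

__all__ = [
    "AlignmentError",
    "CandidatePair",
    "DegeneratePathError",
    "DependencyNode",
    "DependencyTree",
    "ParseTableError",
    "PathSignature",
    "PatternTable",
    "candidate_pairs",
    "distant_label",
    "entity_head",
    "extract_path",
    "learn_patterns",
    "load_parses",
    "read_conll",
    "score_syntax",
]

DEFAULT_THETA = 0.5        # positive-ratio threshold for a "yes" decision
DEFAULT_MIN_SUPPORT = 1
DEFAULT_BACKOFF = 0.25     # score for candidates whose path was never seen


class ParseTableError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class DegeneratePathError(ValueError):
    pass


@dataclass(frozen=True)
class DependencyNode:
    index: int        # 1-based token position
    surface: str
    lemma: str
    pos: str
    head: int         # 0 = root
    label: str        # dependency edge label to the head


@dataclass
class DependencyTree:
    sentence_index: int
    nodes: List[DependencyNode]
    alignment: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    # token index -> (document offset, length)

    def node(self, index: int) -> DependencyNode:
        return self.nodes[index - 1]

    def validate(self) -> None:
        roots = [n for n in self.nodes if n.head == 0]
        if len(roots) != 1:
            raise ParseTableError(
                f"sentence {self.sentence_index}: {len(roots)} roots (expected 1)"
            )
        for n in self.nodes:
            seen = set()
            cur = n.index
            while cur != 0:
                if cur in seen:
                    raise ParseTableError(
                        f"sentence {self.sentence_index}: cyclic head links at token {cur}"
                    )
                seen.add(cur)
                cur = self.node(cur).head

    def chain_to_root(self, index: int) -> List[int]:
        chain = []
        cur = index
        while cur != 0:
            chain.append(cur)
            cur = self.node(cur).head
        return chain


@dataclass(frozen=True)
class PathSignature:
    top_lemma: str
    left_path: Tuple[str, ...]
    right_path: Tuple[str, ...]


@dataclass
class CandidatePair:
    document_id: str
    sentence_index: int
    a: BioCAnnotation   # left entity by surface order
    b: BioCAnnotation
    syntactic_score: Optional[float] = None
    pattern: Optional[PathSignature] = None

    @property
    def concept_pair(self) -> frozenset:
        return frozenset((self.a.infons["concept_id"], self.b.infons["concept_id"]))

    @property
    def type_pair(self) -> frozenset:
        return frozenset((self.a.infons["type"], self.b.infons["type"]))


# ---------------------------------------------------------------------------
# parse input

def read_conll(source: Union[str, io.IOBase]) -> List[List[DependencyNode]]:
    """Read blank-line-separated 6-column blocks (index surface lemma pos head label)."""
    if isinstance(source, str) and ("\t" in source or "\n" in source):
        fh = io.StringIO(source)
    elif isinstance(source, str):
        fh = open(source, encoding="utf-8")
    else:
        fh = source
    blocks: List[List[DependencyNode]] = []
    current: List[DependencyNode] = []
    with fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                if current:
                    blocks.append(current)
                    current = []
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseTableError(f"expected 6 columns, got {len(fields)}: {line!r}")
            current.append(DependencyNode(
                index=int(fields[0]), surface=fields[1], lemma=fields[2],
                pos=fields[3], head=int(fields[4]), label=fields[5],
            ))
    if current:
        blocks.append(current)
    return blocks


def _align_tokens(nodes: Sequence, sentence_text: str, sentence_offset: int,
                  sentence_index: int) -> Dict[int, Tuple[int, int]]:
    alignment = {}
    cursor = 0
    for n in nodes:
        pos = sentence_text.find(n.surface, cursor)
        if pos < 0:
            raise AlignmentError(
                f"sentence {sentence_index}: token {n.surface!r} not found in text"
            )
        alignment[n.index] = (sentence_offset + pos, len(n.surface))
        cursor = pos + len(n.surface)
    return alignment


def load_parses(source: Union[str, io.IOBase, list], document: BioCDocument) -> list:
    """Build document-aligned dependency trees from a CoNLL-style table.

    Blocks pair with the document's sentences by order; token surfaces are
    located left-to-right in the sentence text to recover document
    offsets.  Raises on root-count/cycle violations and on block/sentence
    count mismatch or unlocatable tokens.
    """
    blocks = source if isinstance(source, list) else read_conll(source)
    sentences = list(document.sentences())
    if len(blocks) != len(sentences):
        raise AlignmentError(
            f"document '{document.id}': {len(blocks)} parse blocks for "
            f"{len(sentences)} sentences"
        )
    trees = []
    for sent, nodes in zip(sentences, blocks):
        tree = DependencyTree(sentence_index=sent.index, nodes=list(nodes))
        tree.validate()
        tree.alignment = _align_tokens(nodes, sent.text, sent.offset, sent.index)
        trees.append(tree)
    return trees


# ---------------------------------------------------------------------------
# path extraction

def extract_path(tree: DependencyTree, head_a: int, head_b: int) -> PathSignature:
    """Dependency path signature between two entity head tokens.

    The LCA over head links supplies the top lemma; the left/right paths
    are the downward edge-label sequences from the LCA to ``head_a`` /
    ``head_b`` (the caller orders the heads by surface position).  An
    entity whose head *is* the LCA contributes an empty path on its side.
    """
    if head_a == head_b:
        raise DegeneratePathError(f"identical head token {head_a}")
    chain_a = tree.chain_to_root(head_a)
    chain_b = tree.chain_to_root(head_b)
    set_a = set(chain_a)
    lca = next(n for n in chain_b if n in set_a)

    def down_labels(chain: List[int]) -> Tuple[str, ...]:
        labels = [tree.node(i).label for i in chain[: chain.index(lca)]]
        return tuple(reversed(labels))

    return PathSignature(
        top_lemma=tree.node(lca).lemma,
        left_path=down_labels(chain_a),
        right_path=down_labels(chain_b),
    )


def entity_head(tree: DependencyTree, ann: BioCAnnotation) -> Optional[int]:
    """Head token of a (possibly multi-token) entity span.

    The token inside the span whose governor lies outside it is the
    syntactic head; if the parse does not determine one uniquely the last
    token of the span is used (English biomedical names are head-final).
    """
    inside = [i for i, (off, length) in sorted(tree.alignment.items())
              if off >= ann.offset and off + length <= ann.end]
    if not inside:
        return None
    span = set(inside)
    external = [i for i in inside if tree.node(i).head not in span]
    if len(external) == 1:
        return external[0]
    return inside[-1]


# ---------------------------------------------------------------------------
# candidates and distant supervision

def _normalize_pair_spec(type_pairs: Iterable) -> set:
    return {frozenset(p) for p in type_pairs}


def candidate_pairs(annotations: Sequence, type_pairs: Iterable,
                    document_id: str = "", allow_self: bool = False) -> list:
    """Co-occurrence candidates: unordered annotation pairs per sentence.

    One candidate per pair of distinct annotations in the same sentence
    whose entity types match a requested (unordered) pair; pairs with the
    same resolved concept id are suppressed unless ``allow_self``.
    Members are ordered by surface position.
    """
    spec = _normalize_pair_spec(type_pairs)
    by_sentence: Dict[int, list] = {}
    for ann in annotations:
        idx = ann.infons.get("sentence_index")
        if idx is not None:
            by_sentence.setdefault(int(idx), []).append(ann)
    pairs = []
    for idx in sorted(by_sentence):
        anns = sorted(by_sentence[idx], key=lambda a: (a.offset, a.infons["concept_id"]))
        for i in range(len(anns)):
            for j in range(i + 1, len(anns)):
                a, b = anns[i], anns[j]
                if frozenset((a.infons["type"], b.infons["type"])) not in spec:
                    continue
                if not allow_self and a.infons["concept_id"] == b.infons["concept_id"]:
                    continue
                pairs.append(CandidatePair(document_id, idx, a, b))
    return pairs


def distant_label(document: BioCDocument, annotations: Sequence,
                  gold_db: set) -> Dict[int, str]:
    """Label each sentence positive/negative by projecting a gold database.

    A sentence is positive iff it contains at least one pair of entities
    whose unordered concept-id pair belongs to a gold interaction recorded
    for this document; every other sentence is negative.
    """
    gold_pairs = {frozenset((a, b)) for d, a, b in gold_db if d == document.id}
    by_sentence: Dict[int, set] = {s.index: set() for s in document.sentences()}
    for ann in annotations:
        idx = ann.infons.get("sentence_index")
        if idx is not None:
            by_sentence.setdefault(int(idx), set()).add(ann.infons["concept_id"])
    labels = {}
    for idx, concepts in by_sentence.items():
        ids = sorted(concepts)
        positive = any(
            frozenset((ids[i], ids[j])) in gold_pairs
            for i in range(len(ids)) for j in range(i + 1, len(ids))
        )
        labels[idx] = "positive" if positive else "negative"
    return labels


# ---------------------------------------------------------------------------
# pattern table

class PatternTable:
    """Yes/no decision statistics per dependency-path signature."""

    def __init__(self, theta: float = DEFAULT_THETA,
                 min_support: int = DEFAULT_MIN_SUPPORT):
        self.theta = theta
        self.min_support = min_support
        self.counts: Dict[PathSignature, List[int]] = {}

    def __len__(self) -> int:
        return len(self.counts)

    def add(self, signature: PathSignature, positive: bool) -> None:
        cell = self.counts.setdefault(signature, [0, 0])
        cell[0 if positive else 1] += 1

    def ratio(self, signature: PathSignature) -> float:
        n_pos, n_neg = self.counts[signature]
        return n_pos / (n_pos + n_neg)

    def decision(self, signature: PathSignature) -> str:
        n_pos, n_neg = self.counts[signature]
        if n_pos + n_neg >= self.min_support and self.ratio(signature) >= self.theta:
            return "yes"
        return "no"

    def to_tsv(self) -> str:
        lines = ["top_lemma\tleft_path\tright_path\tn_pos\tn_neg\tdecision"]
        for sig in sorted(self.counts, key=lambda s: (s.top_lemma, s.left_path, s.right_path)):
            n_pos, n_neg = self.counts[sig]
            lines.append("\t".join([
                sig.top_lemma, ",".join(sig.left_path), ",".join(sig.right_path),
                str(n_pos), str(n_neg), self.decision(sig),
            ]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, source: Union[str, io.IOBase], theta: float = DEFAULT_THETA,
                 min_support: int = DEFAULT_MIN_SUPPORT) -> "PatternTable":
        if isinstance(source, str) and ("\t" in source or "\n" in source):
            fh = io.StringIO(source)
        elif isinstance(source, str):
            fh = open(source, encoding="utf-8")
        else:
            fh = source
        table = cls(theta=theta, min_support=min_support)
        with fh:
            header = fh.readline()
            if not header.startswith("top_lemma"):
                raise ParseTableError("pattern table missing header")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                top, left, right, n_pos, n_neg, _decision = line.split("\t")
                sig = PathSignature(
                    top,
                    tuple(left.split(",")) if left else (),
                    tuple(right.split(",")) if right else (),
                )
                table.counts[sig] = [int(n_pos), int(n_neg)]
        return table


def _pair_signature(candidate: CandidatePair, tree: DependencyTree) -> Optional[PathSignature]:
    ha = entity_head(tree, candidate.a)
    hb = entity_head(tree, candidate.b)
    if ha is None or hb is None or ha == hb:
        return None
    return extract_path(tree, ha, hb)


def learn_patterns(corpus: Iterable, gold_db: set,
                   type_pairs: Iterable = ((("protein", "protein")),),
                   mode: str = "pair",
                   theta: float = DEFAULT_THETA,
                   min_support: int = DEFAULT_MIN_SUPPORT) -> PatternTable:
    """Accumulate path statistics over a distantly supervised corpus.

    ``corpus`` yields (document, annotations, trees) triples with trees
    keyed or ordered by sentence index.  In ``pair`` mode a path counts
    positive when its entity pair is a gold interaction for the document;
    in ``sentence`` mode when the sentence as a whole is positive under
    :func:`distant_label`.  Counting is order-independent.
    """
    if mode not in ("pair", "sentence"):
        raise ValueError(f"unknown supervision mode {mode!r}")
    spec = _normalize_pair_spec([("protein", "protein")]) if type_pairs is None \
        else _normalize_pair_spec(type_pairs)
    table = PatternTable(theta=theta, min_support=min_support)
    for document, annotations, trees in corpus:
        tree_by_idx = {t.sentence_index: t for t in trees}
        gold_pairs = {frozenset((a, b)) for d, a, b in gold_db if d == document.id}
        sentence_labels = (distant_label(document, annotations, gold_db)
                           if mode == "sentence" else None)
        for cand in candidate_pairs(annotations, spec, document.id):
            tree = tree_by_idx.get(cand.sentence_index)
            if tree is None:
                continue
            sig = _pair_signature(cand, tree)
            if sig is None:
                continue
            if mode == "pair":
                positive = cand.concept_pair in gold_pairs
            else:
                positive = sentence_labels[cand.sentence_index] == "positive"
            table.add(sig, positive)
    return table


def score_syntax(candidate: CandidatePair, tree: Optional[DependencyTree],
                 patterns: PatternTable,
                 backoff: float = DEFAULT_BACKOFF) -> CandidatePair:
    """Attach the syntactic confidence factor to a candidate (in place).

    Exact hit on a yes-pattern -> its positive ratio; hit on a no-pattern
    -> 0; path unseen in training -> the backoff prior; sentence unparsed
    -> score left absent and the candidate retained (recall-preserving).
    """
    if tree is None:
        candidate.syntactic_score = None
        candidate.pattern = None
        return candidate
    sig = _pair_signature(candidate, tree)
    if sig is None:
        candidate.syntactic_score = None
        candidate.pattern = None
        return candidate
    candidate.pattern = sig
    if sig in patterns.counts:
        candidate.syntactic_score = (
            patterns.ratio(sig) if patterns.decision(sig) == "yes" else 0.0
        )
    else:
        candidate.syntactic_score = backoff
    return candidate
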