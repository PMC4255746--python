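"""Terminology loading and dictionary-based entity annotation.

The matcher is a greedy left-to-right longest-match lexical lookup over
token windows, made variant-tolerant by normalizing both lexicon surfaces
and text spans to a shared key (case, Unicode compatibility forms, Greek
letter names, hyphen/slash/whitespace variation, trailing plurals).
Ambiguity is deliberately preserved at this stage — one annotation per
candidate concept — and resolved downstream.

Short or common-word surfaces (the "folD" gene / "SEX" chemical problem:
a technical term colliding with ordinary language) are flagged
case-sensitive at load time; the disambiguation stage later drops their
matches unless the document spells them exactly as the lexicon does.
"""

from __future__ import annotations

import io
import re
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

from .bioc import BioCAnnotation, BioCLocation, BioCPassage

__all__ = [
    "Lexicon",
    "LexiconEntry",
    "LexiconLoadError",
    "Token",
    "annotate",
    "default_stoplist",
    "load_lexicon",
    "load_stoplist",
    "normalize_surface",
    "tokenize",
]

# Surfaces at or below this length are treated as case-sensitive: short
# symbols (SEX, folD, HIS) collide too easily with ordinary words.
CASE_SENSITIVE_MAX_LEN = 5
DEFAULT_MAX_SPAN = 8  # tokens per match window

LEXICON_COLUMNS = ("surface", "concept_id", "entity_type", "preferred_name", "source_db")

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
_GREEK_TABLE = str.maketrans(_GREEK)

# word = run of letters/digits (underscore counts as punctuation so that
# hyphen/slash/underscore all split); any other non-space char is its own token
_TOKEN_RE = re.compile(r"[^\W_]+|[^\w\s]|_", re.UNICODE)


class LexiconLoadError(ValueError):
    pass


@dataclass(frozen=True)
class Token:
    text: str
    offset: int  # document-relative character offset
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


def tokenize(text: str, base_offset: int = 0) -> list:
    """Split text into word and punctuation tokens.

    Words are maximal runs of letters/digits; hyphens, slashes and other
    punctuation become single-character tokens, so "IL-2-dependent" yields
    IL / - / 2 / - / dependent.  Offsets are document-relative
    (``base_offset`` + position in ``text``); concatenating token texts
    with the original gaps reconstructs the input.
    """
    return [
        Token(m.group(), base_offset + m.start(), m.end() - m.start())
        for m in _TOKEN_RE.finditer(text)
    ]


def _strip_plural(key: str) -> str:
    if len(key) > 3 and key.endswith("s") and not key.endswith("ss"):
        return key[:-1]
    return key


def normalize_surface(surface: str) -> str:
    """Map a term surface to its canonical lookup key.

    Applies, in order: Unicode compatibility folding (NFKC), lowercasing,
    Greek symbol -> name unification (α -> alpha), removal of hyphens,
    slashes and whitespace, and trailing-plural stripping on the joined
    key when it is longer than 3 characters (keys ending in "ss" are left
    alone so the rule is idempotent).  Deterministic and idempotent.
    """
    key = unicodedata.normalize("NFKC", surface).lower().translate(_GREEK_TABLE)
    key = re.sub(r"[\s\-/]+", "", key)
    # removal can juxtapose combining marks with new bases; re-fold so the
    # mapping is idempotent
    key = unicodedata.normalize("NFKC", key)
    return _strip_plural(key)


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    concept_id: str
    entity_type: str
    preferred_name: str
    source_db: str
    organism_id: Optional[str] = None
    case_sensitive: bool = False

    @property
    def key(self) -> str:
        return normalize_surface(self.surface)


def default_stoplist() -> frozenset:
    return load_stoplist(None)


_STOPLIST_CACHE: dict = {}


def load_stoplist(path: Optional[str] = None, top_n: Optional[int] = None) -> frozenset:
    """Load the common-word stoplist (one word per line, '#' comments).

    ``path=None`` uses the packaged default list; ``top_n`` truncates to
    the first N lines for callers that want a shorter list.
    """
    cache_key = (path, top_n)
    if cache_key in _STOPLIST_CACHE:
        return _STOPLIST_CACHE[cache_key]
    if path is None:
        text = resources.files("litmine.data").joinpath("stoplist.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    words = [w.strip().lower() for w in text.splitlines()
             if w.strip() and not w.startswith("#")]
    if top_n is not None:
        words = words[:top_n]
    result = frozenset(words)
    _STOPLIST_CACHE[cache_key] = result
    return result


class Lexicon:
    """A terminology: entries indexed by normalized surface key."""

    def __init__(self, entries: Iterable = (), stoplist: Optional[frozenset] = None):
        self.stoplist = default_stoplist() if stoplist is None else stoplist
        self.entries: list = []
        self.index: dict = {}  # normalized key -> list[LexiconEntry]
        self._seen: set = set()
        for e in entries:
            self.add(e)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def types_available(self) -> set:
        return {e.entity_type for e in self.entries}

    def is_case_sensitive_surface(self, surface: str) -> bool:
        return len(surface) <= CASE_SENSITIVE_MAX_LEN or surface.lower() in self.stoplist

    def add(self, entry: LexiconEntry) -> None:
        triple = (entry.surface, entry.concept_id, entry.entity_type)
        if triple in self._seen:  # duplicate rows collapse
            return
        self._seen.add(triple)
        entry = replace(entry, case_sensitive=self.is_case_sensitive_surface(entry.surface))
        self.entries.append(entry)
        self.index.setdefault(entry.key, []).append(entry)

    def lookup(self, key: str) -> list:
        return self.index.get(key, [])

    def to_tsv(self) -> str:
        lines = ["\t".join(LEXICON_COLUMNS + ("organism_id",))]
        for e in self.entries:
            lines.append("\t".join([
                e.surface, e.concept_id, e.entity_type, e.preferred_name,
                e.source_db, e.organism_id or "",
            ]))
        return "\n".join(lines) + "\n"


def load_lexicon(source: Union[str, io.IOBase], stoplist: Optional[frozenset] = None,
                 logger=None) -> Lexicon:
    """Load a lexicon from 5/6-column TSV (header required).

    Required columns: surface, concept_id, entity_type, preferred_name,
    source_db; an optional organism_id column carries the species a
    gene/protein identifier belongs to.  Rows with an empty surface are
    rejected and logged; duplicate (surface, concept, type) rows collapse.
    """
    if isinstance(source, str) and ("\t" in source or "\n" in source):
        fh = io.StringIO(source)
    elif isinstance(source, str):
        fh = open(source, encoding="utf-8")
    else:
        fh = source
    try:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in LEXICON_COLUMNS if c not in header]
        if missing:
            raise LexiconLoadError(f"lexicon table missing column(s): {', '.join(missing)}")
        col = {name: i for i, name in enumerate(header)}
        lex = Lexicon(stoplist=stoplist)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            surface = fields[col["surface"]].strip()
            if not surface:
                if logger is not None:
                    logger.warning("lexicon line %d: empty surface, row rejected", lineno)
                continue
            organism = None
            if "organism_id" in col and len(fields) > col["organism_id"]:
                organism = fields[col["organism_id"]].strip() or None
            lex.add(LexiconEntry(
                surface=surface,
                concept_id=fields[col["concept_id"]].strip(),
                entity_type=fields[col["entity_type"]].strip(),
                preferred_name=fields[col["preferred_name"]].strip(),
                source_db=fields[col["source_db"]].strip(),
                organism_id=organism,
            ))
        return lex
    finally:
        if fh is not source and not isinstance(source, io.IOBase):
            fh.close()


# ---------------------------------------------------------------------------
# Matching

def _entry_to_annotation(entry: LexiconEntry, offset: int, length: int, covered: str,
                         sentence_index: Optional[int]) -> BioCAnnotation:
    infons = {
        "type": entry.entity_type,
        "concept_id": entry.concept_id,
        "preferred_name": entry.preferred_name,
        "source_db": entry.source_db,
        "score": "1.0",
        "lexicon_surface": entry.surface,
        "case_sensitive": "true" if entry.case_sensitive else "false",
    }
    if entry.organism_id:
        infons["organism_id"] = entry.organism_id
    if sentence_index is not None:
        infons["sentence_index"] = str(sentence_index)
    return BioCAnnotation(id="", infons=infons,
                          locations=[BioCLocation(offset, length)], text=covered)


def match_tokens(tokens: Sequence, text: str, base_offset: int, lexicon: Lexicon,
                 max_span: int = DEFAULT_MAX_SPAN) -> list:
    """Greedy left-to-right longest-match over token windows.

    Returns (start_token, n_tokens, entries) triples; the window covering
    the most tokens wins and suppresses overlapping shorter matches, with
    left-to-right tie-breaking.
    """
    matches = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for w in range(min(max_span, n - i), 0, -1):
            span_text = text[tokens[i].offset - base_offset : tokens[i + w - 1].end - base_offset]
            entries = lexicon.lookup(normalize_surface(span_text))
            if entries:
                hit = (i, w, entries)
                break
        if hit:
            matches.append(hit)
            i += hit[1]
        else:
            i += 1
    return matches


def annotate(passage: BioCPassage, lexicon: Lexicon,
             requested_types: Optional[set] = None,
             max_span: int = DEFAULT_MAX_SPAN) -> list:
    """Annotate a passage by dictionary lookup.

    Matching runs per sentence when the passage is segmented (annotations
    never cross sentence boundaries), else over the whole passage text.
    Every matched window yields one annotation per candidate concept —
    ambiguity is preserved for the disambiguation stage — and the
    ``requested_types`` restriction is applied at emission, after
    matching, so restricting types commutes with post-hoc filtering.
    """
    units = ([(s.text, s.offset, s.index) for s in passage.sentences]
             if passage.sentences
             else [(passage.effective_text, passage.offset, None)])
    annotations: list = []
    for text, base, sent_index in units:
        tokens = tokenize(text, base)
        for i, w, entries in match_tokens(tokens, text, base, lexicon, max_span):
            start = tokens[i].offset
            end = tokens[i + w - 1].end
            covered = text[start - base : end - base]
            for entry in entries:
                if requested_types is not None and entry.entity_type not in requested_types:
                    continue
                annotations.append(
                    _entry_to_annotation(entry, start, end - start, covered, sent_index)
                )
    return annotations
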