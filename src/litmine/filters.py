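"""Sentence filters: boolean conditions over a sentence's annotations.

Curators triage long articles by writing a condition such as

    has_type(chemical) AND has_type(disease)

and reading only the sentences that satisfy it.  The language has four
atoms — has_type(T), has_concept(ID), has_term(KEY), has_relation(T1,T2)
— combined with NOT > AND > OR (keywords case-insensitive) and
parentheses.  ``apply_filter`` reports the selected sentence indices plus
a reduction ratio measured in characters (how much of the article the
curator still has to read).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Tuple

from .bioc import BioCDocument
from .terminology import normalize_surface

__all__ = [
    "And",
    "Atom",
    "FilterExpression",
    "FilterSyntaxError",
    "Not",
    "Or",
    "apply_filter",
    "parse_filter",
    "sentence_matches",
]

ATOM_NAMES = ("has_type", "has_concept", "has_term", "has_relation")


class FilterSyntaxError(ValueError):
    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


class FilterExpression:
    def evaluate(self, sentence_annotations) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Atom(FilterExpression):
    name: str
    args: Tuple[str, ...]

    def evaluate(self, anns) -> bool:
        if self.name == "has_type":
            return any(a.infons["type"] == self.args[0] for a in anns)
        if self.name == "has_concept":
            return any(a.infons["concept_id"] == self.args[0] for a in anns)
        if self.name == "has_term":
            key = normalize_surface(self.args[0])
            return any(normalize_surface(a.text) == key for a in anns)
        # has_relation(T1, T2): two distinct annotations realizing the type pair
        t1, t2 = self.args
        if t1 == t2:
            return sum(1 for a in anns if a.infons["type"] == t1) >= 2
        return (any(a.infons["type"] == t1 for a in anns)
                and any(a.infons["type"] == t2 for a in anns))

    def __str__(self) -> str:
        return f"{self.name}({', '.join(self.args)})"


@dataclass(frozen=True)
class Not(FilterExpression):
    operand: FilterExpression

    def evaluate(self, anns) -> bool:
        return not self.operand.evaluate(anns)

    def __str__(self) -> str:
        return f"NOT {self._wrap(self.operand)}"

    @staticmethod
    def _wrap(e) -> str:
        return f"({e})" if isinstance(e, (And, Or)) else str(e)


@dataclass(frozen=True)
class And(FilterExpression):
    left: FilterExpression
    right: FilterExpression

    def evaluate(self, anns) -> bool:
        return self.left.evaluate(anns) and self.right.evaluate(anns)

    def __str__(self) -> str:
        def wrap(e):
            return f"({e})" if isinstance(e, Or) else str(e)
        return f"{wrap(self.left)} AND {wrap(self.right)}"


@dataclass(frozen=True)
class Or(FilterExpression):
    left: FilterExpression
    right: FilterExpression

    def evaluate(self, anns) -> bool:
        return self.left.evaluate(anns) or self.right.evaluate(anns)

    def __str__(self) -> str:
        return f"{self.left} OR {self.right}"


_TOKEN_RE = re.compile(r"\s*(\(|\)|,|[A-Za-z_][A-Za-z0-9_\-]*|\S)")


class _Parser:
    """Recursive descent for: or := and (OR and)*, and := not (AND not)*,
    not := NOT not | primary, primary := atom | '(' or ')'."""

    def __init__(self, text: str, known_types: Optional[set] = None):
        self.text = text
        self.pos = 0
        self.known_types = known_types

    def _error(self, message: str):
        raise FilterSyntaxError(message, self.pos + 1)

    def _peek(self) -> Optional[str]:
        m = _TOKEN_RE.match(self.text, self.pos)
        return m.group(1) if m else None

    def _next(self) -> Optional[str]:
        m = _TOKEN_RE.match(self.text, self.pos)
        if not m:
            return None
        self.pos = m.end()
        return m.group(1)

    def parse(self) -> FilterExpression:
        expr = self._or()
        if self._peek() is not None:
            self._error(f"unexpected input {self._peek()!r}")
        return expr

    def _or(self) -> FilterExpression:
        left = self._and()
        while (tok := self._peek()) is not None and tok.upper() == "OR":
            self._next()
            left = Or(left, self._and())
        return left

    def _and(self) -> FilterExpression:
        left = self._not()
        while (tok := self._peek()) is not None and tok.upper() == "AND":
            self._next()
            left = And(left, self._not())
        return left

    def _not(self) -> FilterExpression:
        tok = self._peek()
        if tok is not None and tok.upper() == "NOT":
            self._next()
            return Not(self._not())
        return self._primary()

    def _primary(self) -> FilterExpression:
        tok = self._peek()
        if tok is None:
            self._error("unexpected end of expression")
        if tok == "(":
            self._next()
            expr = self._or()
            if self._peek() != ")":
                self._error("expected ')'")
            self._next()
            return expr
        if tok.lower() in ATOM_NAMES:
            return self._atom(tok.lower())
        self._error(f"expected atom or '(', got {tok!r}")

    def _atom(self, name: str) -> Atom:
        self._next()
        if self._peek() != "(":
            self._error(f"expected '(' after {name}")
        self._next()
        args = []
        while True:
            tok = self._peek()
            if tok is None:
                self._error("unterminated atom argument list")
            if tok == ")":
                break
            self._next()
            if tok != ",":
                args.append(tok)
        self._next()  # ')'
        expected = 2 if name == "has_relation" else 1
        if len(args) != expected:
            self._error(f"{name} takes {expected} argument(s), got {len(args)}")
        if name in ("has_type", "has_relation") and self.known_types is not None:
            for t in args:
                if t not in self.known_types:
                    raise FilterSyntaxError(f"unknown entity type {t!r}", self.pos)
        return Atom(name, tuple(args))


def parse_filter(expression: str, known_types: Optional[set] = None) -> FilterExpression:
    """Parse a filter expression; syntax errors carry a column position."""
    return _Parser(expression, known_types).parse()


def sentence_matches(sentence, expr: FilterExpression) -> bool:
    return expr.evaluate(sentence.annotations)


def apply_filter(document: BioCDocument, expr: FilterExpression) -> Tuple[list, float]:
    """Select the sentences satisfying the filter.

    Returns (sorted sentence indices, reduction ratio), the ratio being
    selected characters / total characters over the document's sentences
    (how much text survives the triage).
    """
    selected = []
    total_chars = 0
    kept_chars = 0
    for s in document.sentences():
        total_chars += len(s.text)
        if expr.evaluate(s.annotations):
            selected.append(s.index)
            kept_chars += len(s.text)
    ratio = kept_chars / total_chars if total_chars else 0.0
    return selected, ratio
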