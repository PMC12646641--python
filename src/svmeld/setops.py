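"""Boolean set expressions over supporting-caller sets.

Grammar (case-insensitive keywords, standard precedence NOT > AND > OR;
``NOT`` between two terms is binary set difference, ``a NOT b == a AND NOT b``)::

    expr     := diff (OR diff)*
    diff     := conj (NOT conj)*
    conj     := unary (AND unary)*
    unary    := NOT unary | atom
    atom     := '(' expr ')' | min_support '(' INT ')'
              | max_support '(' INT ')' | CALLER_NAME

``min_support(k)`` / ``max_support(k)`` are support-count predicates; union
is ``min_support(1)`` and intersection of N callers is ``min_support(N)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .merge import MergedRecord

__all__ = [
    "SetExpression",
    "Caller",
    "And",
    "Or",
    "Not",
    "MinSupport",
    "MaxSupport",
    "ExpressionSyntaxError",
    "UnknownCallerError",
    "parse_expression",
    "apply_set_operation",
]


class ExpressionSyntaxError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnknownCallerError(ValueError):
    def __init__(self, name: str):
        super().__init__(f"unknown caller identifier: {name!r}")
        self.name = name


class SetExpression:
    """Base class; subclasses form the expression tree."""

    def evaluate(self, support: frozenset[str] | set[str]) -> bool:
        raise NotImplementedError

    def callers(self) -> set[str]:
        return set()

    def to_text(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_text()})"


@dataclass(repr=False)
class Caller(SetExpression):
    name: str

    def evaluate(self, support):
        return self.name in support

    def callers(self):
        return {self.name}

    def to_text(self):
        return self.name


@dataclass(repr=False)
class MinSupport(SetExpression):
    k: int

    def evaluate(self, support):
        return len(support) >= self.k

    def to_text(self):
        return f"min_support({self.k})"


@dataclass(repr=False)
class MaxSupport(SetExpression):
    k: int

    def evaluate(self, support):
        return len(support) <= self.k

    def to_text(self):
        return f"max_support({self.k})"


@dataclass(repr=False)
class And(SetExpression):
    left: SetExpression
    right: SetExpression

    def evaluate(self, support):
        return self.left.evaluate(support) and self.right.evaluate(support)

    def callers(self):
        return self.left.callers() | self.right.callers()

    def to_text(self):
        return f"({self.left.to_text()} AND {self.right.to_text()})"


@dataclass(repr=False)
class Or(SetExpression):
    left: SetExpression
    right: SetExpression

    def evaluate(self, support):
        return self.left.evaluate(support) or self.right.evaluate(support)

    def callers(self):
        return self.left.callers() | self.right.callers()

    def to_text(self):
        return f"({self.left.to_text()} OR {self.right.to_text()})"


@dataclass(repr=False)
class Not(SetExpression):
    operand: SetExpression

    def evaluate(self, support):
        return not self.operand.evaluate(support)

    def callers(self):
        return self.operand.callers()

    def to_text(self):
        return f"(NOT {self.operand.to_text()})"


_TOKEN_RE = re.compile(r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<int>\d+)|"
                       r"(?P<ident>[A-Za-z_][A-Za-z0-9_.\-]*))")

_KEYWORDS = {"and", "or", "not"}
_PREDICATES = {"min_support", "max_support"}


@dataclass
class _Token:
    kind: str  # lparen rparen int ident and or not min_support max_support eof
    text: str
    offset: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == m.start():
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ExpressionSyntaxError(
                f"unexpected character {stripped[0]!r}",
                len(text) - len(stripped),
            )
        offset = m.start(m.lastgroup)
        value = m.group(m.lastgroup)
        kind = m.lastgroup
        if kind == "ident":
            lowered = value.lower()
            if lowered in _KEYWORDS or lowered in _PREDICATES:
                kind = lowered
        tokens.append(_Token(kind, value, offset))
        pos = m.end()
    tokens.append(_Token("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        tok = self.peek()
        if tok.kind != kind:
            raise ExpressionSyntaxError(f"expected {what}", tok.offset)
        return self.advance()

    def parse(self) -> SetExpression:
        expr = self.or_expr()
        tok = self.peek()
        if tok.kind != "eof":
            raise ExpressionSyntaxError(f"unexpected token {tok.text!r}", tok.offset)
        return expr

    def or_expr(self) -> SetExpression:
        node = self.diff_expr()
        while self.peek().kind == "or":
            self.advance()
            node = Or(node, self.diff_expr())
        return node

    def diff_expr(self) -> SetExpression:
        node = self.and_expr()
        while self.peek().kind == "not":
            self.advance()
            node = And(node, Not(self.and_expr()))
        return node

    def and_expr(self) -> SetExpression:
        node = self.unary()
        while self.peek().kind == "and":
            self.advance()
            node = And(node, self.unary())
        return node

    def unary(self) -> SetExpression:
        tok = self.peek()
        if tok.kind == "not":
            self.advance()
            return Not(self.unary())
        return self.atom()

    def atom(self) -> SetExpression:
        tok = self.peek()
        if tok.kind == "lparen":
            self.advance()
            node = self.or_expr()
            self.expect("rparen", "')'")
            return node
        if tok.kind in ("min_support", "max_support"):
            self.advance()
            self.expect("lparen", "'('")
            k = int(self.expect("int", "integer").text)
            self.expect("rparen", "')'")
            return MinSupport(k) if tok.kind == "min_support" else MaxSupport(k)
        if tok.kind == "ident":
            self.advance()
            return Caller(tok.text)
        raise ExpressionSyntaxError("expected caller name, predicate or '('", tok.offset)


def parse_expression(text: str) -> SetExpression:
    """Parse an expression string into a :class:`SetExpression` tree."""
    return _Parser(_tokenize(text)).parse()


def apply_set_operation(
    merged: Iterable[MergedRecord],
    expr: SetExpression | str,
    known_callers: Sequence[str] | None = None,
) -> list[MergedRecord]:
    """Retain exactly the consensus records whose support set satisfies *expr*.

    Caller names referenced by the expression must exist in the provenance
    (pass *known_callers* or it is derived from the records).
    """
    merged = list(merged)
    if isinstance(expr, str):
        expr = parse_expression(expr)
    if known_callers is None:
        known = set()
        for m in merged:
            known |= m.support
    else:
        known = set(known_callers)
    for name in sorted(expr.callers()):
        if name not in known:
            raise UnknownCallerError(name)
    return [m for m in merged if expr.evaluate(m.support)]
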