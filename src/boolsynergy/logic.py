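"""Boolean rule expressions: AST, infix parser, and vectorised evaluation.

Update rules are logic formulas over node names with the operators AND, OR and
NOT (case-insensitive, parenthesised, infix), e.g. ``(A or B) and not C``.
Expressions are parsed into a small immutable AST that can be evaluated on a
single ``{node: 0/1}`` state or compiled into a NumPy function operating on a
``(repeats, n_nodes)`` boolean matrix — the representation the asynchronous
simulator uses to advance many trajectories at once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Expr",
    "Var",
    "Not",
    "And",
    "Or",
    "parse_expression",
    "ParseError",
]


class Expr:
    """Base class for rule expressions."""

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def compile(self, index: Mapping[str, int]) -> Callable[[np.ndarray], np.ndarray]:
        """Return ``f(S) -> bool vector`` for a (repeats, n_nodes) bool matrix S."""
        raise NotImplementedError

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError


@dataclass(frozen=True, eq=False)
class Var(Expr):
    name: str

    def variables(self):
        return frozenset({self.name})

    def evaluate(self, state):
        return int(bool(state[self.name]))

    def compile(self, index):
        j = index[self.name]
        return lambda S: S[:, j]

    def _key(self):
        return self.name

    def __str__(self):
        return self.name


@dataclass(frozen=True, eq=False)
class Not(Expr):
    operand: Expr

    def variables(self):
        return self.operand.variables()

    def evaluate(self, state):
        return 1 - self.operand.evaluate(state)

    def compile(self, index):
        f = self.operand.compile(index)
        return lambda S: ~f(S)

    def _key(self):
        return self.operand

    def __str__(self):
        inner = str(self.operand)
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"not {inner}"


class _NaryOp(Expr):
    """Shared machinery for AND/OR over two or more operands."""

    _symbol: str
    _reduce: Callable

    def __init__(self, *operands: Expr):
        if len(operands) < 2:
            raise ValueError(f"{type(self).__name__} needs at least two operands")
        # associative flattening: And(And(a,b),c) == And(a,b,c)
        flat: list[Expr] = []
        for op in operands:
            if type(op) is type(self):
                flat.extend(op.operands)  # type: ignore[attr-defined]
            else:
                flat.append(op)
        self.operands: tuple[Expr, ...] = tuple(flat)

    def variables(self):
        return frozenset().union(*(o.variables() for o in self.operands))

    def _key(self):
        return self.operands

    def __repr__(self):
        args = ", ".join(repr(o) for o in self.operands)
        return f"{type(self).__name__}({args})"

    def __str__(self):
        parts = []
        for o in self.operands:
            s = str(o)
            if isinstance(o, _NaryOp) and type(o) is not type(self):
                s = f"({s})"
            parts.append(s)
        return f" {self._symbol} ".join(parts)


class And(_NaryOp):
    _symbol = "and"

    def evaluate(self, state):
        return int(all(o.evaluate(state) for o in self.operands))

    def compile(self, index):
        fns = [o.compile(index) for o in self.operands]

        def f(S):
            out = fns[0](S)
            for g in fns[1:]:
                out = out & g(S)
            return out

        return f


class Or(_NaryOp):
    _symbol = "or"

    def evaluate(self, state):
        return int(any(o.evaluate(state) for o in self.operands))

    def compile(self, index):
        fns = [o.compile(index) for o in self.operands]

        def f(S):
            out = fns[0](S)
            for g in fns[1:]:
                out = out | g(S)
            return out

        return f


class ParseError(ValueError):
    """Raised when a rule expression string is malformed."""


# Node names may carry the merge suffixes (_c, _i), dots, digits, '+' and '-'
# (CAS registry numbers appear as drug identifiers elsewhere; protein nodes are
# plain identifiers, but the token class is kept permissive).
_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.+\-/]+)")
_KEYWORDS = {"and": "AND", "or": "OR", "not": "NOT"}


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[pos]!r} at position {pos}")
        tok = m.group(1)
        tokens.append(_KEYWORDS.get(tok.lower(), tok))
        pos = m.end()
    return tokens


class _Parser:
    # Grammar (standard precedence NOT > AND > OR):
    #   or_expr  := and_expr (OR and_expr)*
    #   and_expr := not_expr (AND not_expr)*
    #   not_expr := NOT not_expr | atom
    #   atom     := '(' or_expr ')' | NAME

    def __init__(self, tokens: Sequence[str], text: str):
        self.tokens = list(tokens)
        self.pos = 0
        self.text = text

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def advance(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, tok: str):
        got = self.advance()
        if got != tok:
            raise ParseError(f"expected {tok!r}, got {got!r} in {self.text!r}")

    def parse(self) -> Expr:
        expr = self.or_expr()
        if self.peek() is not None:
            raise ParseError(f"trailing tokens after expression in {self.text!r}")
        return expr

    def or_expr(self) -> Expr:
        operands = [self.and_expr()]
        while self.peek() == "OR":
            self.advance()
            operands.append(self.and_expr())
        return operands[0] if len(operands) == 1 else Or(*operands)

    def and_expr(self) -> Expr:
        operands = [self.not_expr()]
        while self.peek() == "AND":
            self.advance()
            operands.append(self.not_expr())
        return operands[0] if len(operands) == 1 else And(*operands)

    def not_expr(self) -> Expr:
        if self.peek() == "NOT":
            self.advance()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> Expr:
        tok = self.advance()
        if tok == "(":
            inner = self.or_expr()
            self.expect(")")
            return inner
        if tok is None or tok in (")", "AND", "OR", "NOT"):
            raise ParseError(
                f"expected a node name or '(', got {tok!r} in {self.text!r}"
            )
        return Var(tok)


def parse_expression(text: str) -> Expr:
    """Parse an infix AND/OR/NOT rule string into an :class:`Expr` tree."""
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty expression")
    return _Parser(tokens, text).parse()
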