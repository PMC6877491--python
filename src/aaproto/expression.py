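"""The test-attribute expression language of ``aa-when``.

Conditionals test named variables written earlier in the protocol, e.g.
``test="myVariable=='myValue'"`` or ``test="random_choice==2"``.  The
grammar is a small, deliberate superset of the equality tests that appear
in worked protocols: six comparison operators, ``&&``/``||``/``!`` and
parentheses, so that protocols branching on numeric answers can be written
directly.

Evaluation is *total*: it never raises.  A variable missing from the store
makes any comparison involving it false (``!=`` included) and records a
warning — a faulty protocol keeps running, and the linter exists to catch
the fault statically beforehand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional, Union

__all__ = [
    "ExpressionSyntaxError",
    "Literal",
    "Var",
    "Compare",
    "Logical",
    "Expr",
    "parse_expr",
    "eval_expr",
    "format_expr",
    "expr_variables",
]


class ExpressionSyntaxError(ValueError):
    """Unparseable test expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass(frozen=True)
class Literal:
    value: Union[str, float]

    @property
    def is_number(self) -> bool:
        return isinstance(self.value, float)


@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Compare:
    op: str  # == != < <= > >=
    lhs: "Expr"
    rhs: "Expr"


@dataclass(frozen=True)
class Logical:
    op: str  # and / or / not
    operands: tuple["Expr", ...]


Expr = Union[Literal, Var, Compare, Logical]

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>-?\d+(?:\.\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<string>'(?:[^'\\]|\\.)*')
  | (?P<op>==|!=|<=|>=|&&|\|\||[<>!()])
    """,
    re.VERBOSE,
)

_CMP_OPS = ("==", "!=", "<=", ">=", "<", ">")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ExpressionSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent with precedence  !  >  comparison  >  &&  >  ||."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise ExpressionSyntaxError("unexpected end of expression", len(self.text))
        self.index += 1
        return tok

    def expect_op(self, op: str) -> None:
        tok = self.peek()
        if tok is None or tok[0] != "op" or tok[1] != op:
            pos = tok[2] if tok else len(self.text)
            raise ExpressionSyntaxError(f"expected {op!r}", pos)
        self.index += 1

    def parse(self) -> Expr:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise ExpressionSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> Expr:
        operands = [self.parse_and()]
        while self._at_op("||"):
            self.index += 1
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else Logical("or", tuple(operands))

    def parse_and(self) -> Expr:
        operands = [self.parse_unary()]
        while self._at_op("&&"):
            self.index += 1
            operands.append(self.parse_unary())
        return operands[0] if len(operands) == 1 else Logical("and", tuple(operands))

    def parse_unary(self) -> Expr:
        if self._at_op("!"):
            self.index += 1
            return Logical("not", (self.parse_unary(),))
        return self.parse_comparison()

    def parse_comparison(self) -> Expr:
        if self._at_op("("):
            self.index += 1
            inner = self.parse_or()
            self.expect_op(")")
            return inner
        lhs = self.parse_operand()
        tok = self.peek()
        if tok is not None and tok[0] == "op" and tok[1] in _CMP_OPS:
            self.index += 1
            rhs = self.parse_operand()
            return Compare(tok[1], lhs, rhs)
        return lhs

    def parse_operand(self) -> Expr:
        kind, text, pos = self.next()
        if kind == "number":
            return Literal(float(text))
        if kind == "string":
            body = text[1:-1]
            return Literal(re.sub(r"\\(.)", r"\1", body))
        if kind == "ident":
            return Var(text)
        raise ExpressionSyntaxError(f"expected a value, found {text!r}", pos)

    def _at_op(self, op: str) -> bool:
        tok = self.peek()
        return tok is not None and tok[0] == "op" and tok[1] == op


def parse_expr(text: str) -> Expr:
    """Parse a test expression; raises :class:`ExpressionSyntaxError` with
    the offending character position."""
    if not text.strip():
        raise ExpressionSyntaxError("empty expression", 0)
    return _Parser(text).parse()


# --------------------------------------------------------------------------
# evaluation

_MISSING = object()


def _as_number(value) -> Optional[float]:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    try:
        return float(str(value).strip())
    except (TypeError, ValueError):
        return None


def _compare(op: str, left, right) -> bool:
    ln, rn = _as_number(left), _as_number(right)
    if ln is not None and rn is not None:
        a, b = ln, rn
    else:
        a, b = str(left), str(right)
    if op == "==":
        return a == b
    if op == "!=":
        return a != b
    if op == "<":
        return a < b
    if op == "<=":
        return a <= b
    if op == ">":
        return a > b
    if op == ">=":
        return a >= b
    raise ValueError(f"unknown comparison operator {op!r}")


def _truthy(value) -> bool:
    return str(value).strip().lower() not in ("", "0", "false")


def eval_expr(expr: Expr, store, warn: Optional[Callable[[str], None]] = None) -> bool:
    """Evaluate against a variable store (any mapping-like with ``get``).

    Numeric comparison when both operands parse as numbers, lexicographic
    text comparison otherwise.  A missing variable makes the enclosing
    comparison (or bare-variable test) false and emits a warning through
    ``warn``; evaluation never raises.
    """

    def emit(message: str) -> None:
        if warn is not None:
            warn(message)

    def value_of(node: Expr):
        if isinstance(node, Literal):
            return node.value
        if isinstance(node, Var):
            value = store.get(node.name, _MISSING)
            if value is _MISSING:
                emit(f"variable '{node.name}' is not set; test treated as false")
            return value
        # a nested boolean used as a comparison operand
        return "true" if walk(node) else "false"

    def walk(node: Expr) -> bool:
        if isinstance(node, Compare):
            left, right = value_of(node.lhs), value_of(node.rhs)
            if left is _MISSING or right is _MISSING:
                return False
            return _compare(node.op, left, right)
        if isinstance(node, Logical):
            if node.op == "not":
                return not walk(node.operands[0])
            if node.op == "and":
                return all(walk(o) for o in node.operands)
            return any(walk(o) for o in node.operands)
        value = value_of(node)
        return False if value is _MISSING else _truthy(value)

    return walk(expr)


# --------------------------------------------------------------------------
# introspection


def format_expr(expr: Expr) -> str:
    """Pretty-print an expression; ``parse_expr`` of the output yields an
    equivalent tree (used by tests and diagnostics)."""
    if isinstance(expr, Literal):
        if expr.is_number:
            value = expr.value
            return str(int(value)) if float(value).is_integer() else repr(value)
        escaped = str(expr.value).replace("\\", "\\\\").replace("'", "\\'")
        return f"'{escaped}'"
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Compare):
        return f"{format_expr(expr.lhs)}{expr.op}{format_expr(expr.rhs)}"
    if isinstance(expr, Logical):
        if expr.op == "not":
            return f"!({format_expr(expr.operands[0])})"
        joiner = "&&" if expr.op == "and" else "||"
        return joiner.join(f"({format_expr(o)})" for o in expr.operands)
    raise TypeError(f"not an expression node: {expr!r}")


def expr_variables(expr: Expr) -> set[str]:
    """Names of all variables the expression reads."""
    if isinstance(expr, Var):
        return {expr.name}
    if isinstance(expr, Compare):
        return expr_variables(expr.lhs) | expr_variables(expr.rhs)
    if isinstance(expr, Logical):
        out: set[str] = set()
        for operand in expr.operands:
            out |= expr_variables(operand)
        return out
    return set()
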