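"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule is a boolean expression over gene identifiers, e.g.
``"(SCO1947 and SCO7511) or SCO7638"``.  ``or`` joins isozymes (either gene
product suffices), ``and`` joins subunits of a complex (all required).  This
module parses such rules into a small AST, extracts the gene set, and emits a
canonical infix form so that round-tripped rules compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import DataError

_TOKEN = re.compile(r"\s*(\(|\)|[Aa][Nn][Dd]\b|[Oo][Rr]\b|[^\s()]+)")

#: Placeholder tokens that stand for "gene unknown" in legacy models.  They are
#: kept in the gene set (so reaction-gene accounting stays faithful to the
#: source file) but can be flagged via :func:`is_placeholder`.
_PLACEHOLDER = re.compile(r"^(unknown|none|spontaneous|s\d{4})$", re.IGNORECASE)


@dataclass(frozen=True)
class GeneRef:
    gene: str


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    operands: tuple


def is_placeholder(gene: str) -> bool:
    """True for unknown-gene placeholder tokens (``Unknown``, ``s0001``, ...)."""
    return bool(_PLACEHOLDER.match(gene))


def tokenize(rule: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; ``or`` binds looser than ``and``."""

    def __init__(self, tokens: list[str], rule: str):
        self.tokens = tokens
        self.rule = rule
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise DataError(f"trailing tokens in GPR rule {self.rule!r}")
        return node

    def parse_or(self):
        operands = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else BoolOp("or", tuple(operands))

    def parse_and(self):
        operands = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            operands.append(self.parse_atom())
        return operands[0] if len(operands) == 1 else BoolOp("and", tuple(operands))

    def parse_atom(self):
        tok = self.next()
        if tok is None:
            raise DataError(f"unexpected end of GPR rule {self.rule!r}")
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise DataError(f"unbalanced parentheses in GPR rule {self.rule!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise DataError(f"misplaced token {tok!r} in GPR rule {self.rule!r}")
        return GeneRef(tok)


def parse(rule: str):
    """Parse a GPR rule into an AST; empty/blank rules parse to ``None``."""
    tokens = tokenize(rule)
    if not tokens:
        return None
    return _Parser(tokens, rule).parse()


def genes(rule: str) -> set[str]:
    """The set of gene identifiers occurring anywhere in *rule*."""
    node = parse(rule)
    out: set[str] = set()

    def walk(n):
        if isinstance(n, GeneRef):
            out.add(n.gene)
        elif isinstance(n, BoolOp):
            for o in n.operands:
                walk(o)

    if node is not None:
        walk(node)
    return out


def _emit(node, parent_op: str | None = None) -> str:
    if isinstance(node, GeneRef):
        return node.gene
    parts = sorted(_emit(o, node.op) for o in node.operands)
    joined = f" {node.op} ".join(parts)
    # Parenthesize "or" under "and" (and vice versa) for unambiguous re-parsing.
    if parent_op is not None and parent_op != node.op:
        return f"({joined})"
    return joined


def normalize(rule: str) -> str:
    """Canonical infix form: lowercase operators, sorted operands.

    Logically equivalent rules that differ only in operand order or redundant
    parentheses normalize to the same string, which is what the SBML round-trip
    guarantee compares.
    """
    node = parse(rule)
    return "" if node is None else _emit(node)
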