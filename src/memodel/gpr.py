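"""Boolean gene-protein-reaction (GPR) expressions.

A GPR string uses ``and`` (complex subunits must all be present) and ``or``
(isozymes) over gene loci.  Parsing produces a normalized disjunctive form:
a sorted list of enzyme modules, each module the sorted set of subunit loci.
Normalization applies idempotence and absorption, so it is itself
idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["GPR", "GPRParseError", "parse_gpr"]


class GPRParseError(ValueError):
    """Malformed GPR expression; carries the character position."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPR:
    """Normalized disjunctive form: modules of subunit loci (isozyme alternatives)."""

    modules: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if any(not m for m in self.modules):
            raise ValueError("empty enzyme module")

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(l for m in self.modules for l in m)

    def evaluate(self, present: set[str]) -> bool:
        """Truth value given a set of present genes (used by the test oracle)."""
        return any(all(l in present for l in m) for m in self.modules)

    def without_gene(self, locus: str) -> "GPR | None":
        """Drop modules requiring `locus` (e.g. the artificial gene s0001).

        Returns None when no module survives (the reaction becomes
        spontaneous / unassociated).
        """
        kept = tuple(m for m in self.modules if locus not in m)
        return GPR(_absorb(kept)) if kept else None


_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            raise GPRParseError(f"unexpected character {expr[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over: expr := term ('or' term)*; term := factor ('and' factor)*."""

    def __init__(self, expr: str) -> None:
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression", len(self.expr))
        self.i += 1
        return tok

    def parse(self) -> tuple[tuple[str, ...], ...]:
        modules = self.expr_rule()
        if self.peek() is not None:
            tok, pos = self.peek()
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        return modules

    def expr_rule(self) -> tuple[tuple[str, ...], ...]:
        modules = list(self.term_rule())
        while self.peek() and self.peek()[0].lower() == "or":
            self.next()
            modules.extend(self.term_rule())
        return tuple(modules)

    def term_rule(self) -> tuple[tuple[str, ...], ...]:
        modules = self.factor_rule()
        while self.peek() and self.peek()[0].lower() == "and":
            self.next()
            right = self.factor_rule()
            # distribute: (A or B) and (C or D) -> AC or AD or BC or BD
            modules = tuple(
                tuple(sorted(set(a) | set(b))) for a in modules for b in right
            )
        return modules

    def factor_rule(self) -> tuple[tuple[str, ...], ...]:
        tok, pos = self.next()
        if tok == "(":
            inner = self.expr_rule()
            closing = self.next()
            if closing[0] != ")":
                raise GPRParseError("expected ')'", closing[1])
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        return ((tok,),)


def _absorb(modules: tuple[tuple[str, ...], ...]) -> tuple[tuple[str, ...], ...]:
    """Deduplicate and drop superset modules: (b1) or (b1 and b2) == b1."""
    sets = sorted({frozenset(m) for m in modules}, key=lambda s: (len(s), sorted(s)))
    kept: list[frozenset[str]] = []
    for s in sets:
        if not any(k <= s for k in kept):
            kept.append(s)
    return tuple(sorted(tuple(sorted(s)) for s in kept))


def parse_gpr(expression: str) -> GPR:
    """Parse a Boolean GPR string into normalized disjunctive form."""
    if not expression or not expression.strip():
        raise GPRParseError("empty expression", 0)
    modules = _Parser(expression).parse()
    return GPR(_absorb(modules))
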