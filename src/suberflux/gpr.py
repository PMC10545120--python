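"""Gene-protein-reaction (GPR) boolean rules.

A GPR is an AND/OR tree over gene identifiers describing which gene
products can catalyse a reaction: ``(g1 and g2) or g3`` means an enzyme
complex of g1+g2, or an isoenzyme g3.  The tree is used both structurally
(which genes a model references) and numerically (scoring reactions from
expression data: AND -> min, OR -> max).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Optional, Union

__all__ = ["GPR", "parse_gpr"]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")

Node = Union[str, tuple]  # gene id, or ("and"|"or", [children])


@dataclass(frozen=True)
class GPR:
    """Parsed GPR rule; ``root is None`` means no gene association."""

    root: Optional[Node]

    def __bool__(self) -> bool:
        return self.root is not None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def to_string(self) -> str:
        """Canonical form with explicit parentheses around every n-ary node."""

        def render(node: Node) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            return "(" + f" {op} ".join(render(c) for c in children) + ")"

        return "" if self.root is None else render(self.root)

    def evaluate(self, value: Callable[[str], Optional[float]]) -> Optional[float]:
        """Score the rule: AND -> min, OR -> max of child scores.

        ``value(gene)`` returning None marks an unmeasured gene: it is
        ignored inside OR (the other isoenzymes still count) but poisons
        AND (a complex with an unmeasured subunit scores unknown).
        """

        def walk(node: Node) -> Optional[float]:
            if isinstance(node, str):
                return value(node)
            op, children = node
            scores = [walk(c) for c in children]
            if op == "and":
                if any(s is None for s in scores):
                    return None
                return min(scores)  # type: ignore[type-var]
            known = [s for s in scores if s is not None]
            return max(known) if known else None

        return None if self.root is None else walk(self.root)


def _tokens(rule: str) -> Iterator[str]:
    for tok in _TOKEN.findall(rule):
        yield tok


class _Parser:
    def __init__(self, rule: str):
        self.toks = list(_tokens(rule))
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> str:
        tok = self.toks[self.pos]
        self.pos += 1
        return tok

    # grammar: or_expr := and_expr ("or" and_expr)*
    #          and_expr := atom ("and" atom)*
    #          atom := gene | "(" or_expr ")"
    def or_expr(self) -> Node:
        parts = [self.and_expr()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def and_expr(self) -> Node:
        parts = [self.atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def atom(self) -> Node:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of GPR rule")
        if tok == "(":
            self.next()
            node = self.or_expr()
            if self.peek() != ")":
                raise ValueError("unbalanced parentheses in GPR rule")
            self.next()
            return node
        if tok == ")":
            raise ValueError("unexpected ')' in GPR rule")
        if tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected operator {tok!r} in GPR rule")
        return self.next()


def parse_gpr(rule: Optional[str]) -> GPR:
    """Parse a boolean gene-association string into a :class:`GPR` tree."""
    if rule is None or not rule.strip():
        return GPR(None)
    parser = _Parser(rule)
    node = parser.or_expr()
    if parser.peek() is not None:
        raise ValueError(f"trailing tokens in GPR rule: {rule!r}")
    return GPR(node)
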