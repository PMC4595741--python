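"""Boolean gene-protein-reaction (GPR) expressions.

Grammar: ``expr := term (OR term)*``, ``term := factor (AND factor)*``,
``factor := GENE | '(' expr ')'``.  AND/OR are case-insensitive keywords;
any other token (which may contain ``;``, ``.`` etc., e.g. ``GLN1;2``) is a
gene identifier.
"""

from __future__ import annotations

import re
from typing import FrozenSet, List, Set, Union


class GPRParseError(ValueError):
    pass


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class _And:
    __slots__ = ("children",)

    def __init__(self, children):
        self.children = children


class _Or:
    __slots__ = ("children",)

    def __init__(self, children):
        self.children = children


Node = Union[str, _And, _Or]


def parse_gpr(text: str) -> Node:
    tokens = _TOKEN.findall(text)
    if not tokens:
        raise GPRParseError("empty GPR expression")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect_factor() -> Node:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            pos += 1
            node = expr()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
            pos += 1
            return node
        if tok == ")" or tok.upper() in ("AND", "OR"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        pos += 1
        return tok

    def term() -> Node:
        nonlocal pos
        children = [expect_factor()]
        while peek() is not None and peek().upper() == "AND":
            pos += 1
            children.append(expect_factor())
        return children[0] if len(children) == 1 else _And(children)

    def expr() -> Node:
        nonlocal pos
        children = [term()]
        while peek() is not None and peek().upper() == "OR":
            pos += 1
            children.append(term())
        return children[0] if len(children) == 1 else _Or(children)

    node = expr()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR: {text!r}")
    return node


def _genes(node: Node, out: Set[str]) -> None:
    if isinstance(node, str):
        out.add(node)
    else:
        for child in node.children:
            _genes(child, out)


def gpr_genes(text: str) -> FrozenSet[str]:
    out: Set[str] = set()
    _genes(parse_gpr(text), out)
    return frozenset(out)


def evaluate_gpr(text: str, knocked_out: Set[str]) -> bool:
    """True iff the reaction can still be catalysed with ``knocked_out`` genes absent."""

    def ev(node: Node) -> bool:
        if isinstance(node, str):
            return node not in knocked_out
        if isinstance(node, _And):
            return all(ev(c) for c in node.children)
        return any(ev(c) for c in node.children)

    return ev(parse_gpr(text))
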