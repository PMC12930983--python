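"""Boolean gene–reaction rules (grRules).

A rule is a Boolean expression over gene identifiers with the operators
``and`` / ``or`` (case-insensitive) and parentheses.  ``or`` joins isoenzymes
(any one gene product suffices), ``and`` joins subunits of an enzyme complex
(all are required).  A bare gene id denotes a single-enzyme reaction and the
empty string a spontaneous or orphan reaction, which is always active.
"""

from __future__ import annotations

import re
from typing import Iterable

__all__ = ["GeneRuleError", "rule_genes", "evaluate_gene_rule", "rule_is_valid"]


class GeneRuleError(ValueError):
    """Raised when a gene rule cannot be parsed."""


_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


def _tokenize(rule: str) -> list[str]:
    return _TOKEN.findall(rule)


class _Parser:
    """Recursive-descent parser; ``or`` binds looser than ``and``."""

    def __init__(self, tokens: list[str], deleted: frozenset[str]):
        self.tokens = tokens
        self.pos = 0
        self.deleted = deleted

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GeneRuleError("unexpected end of rule")
        self.pos += 1
        return tok

    def parse(self) -> bool:
        value = self.parse_or()
        if self.peek() is not None:
            raise GeneRuleError(f"unexpected token {self.peek()!r}")
        return value

    def parse_or(self) -> bool:
        value = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            value = self.parse_and() or value
        return value

    def parse_and(self) -> bool:
        value = self.parse_atom()
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            value = self.parse_atom() and value
        return value

    def parse_atom(self) -> bool:
        tok = self.take()
        if tok == "(":
            value = self.parse_or()
            if self.take() != ")":
                raise GeneRuleError("unbalanced parentheses")
            return value
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GeneRuleError(f"unexpected token {tok!r}")
        return tok not in self.deleted


def evaluate_gene_rule(rule: str, deleted: Iterable[str] = ()) -> bool:
    """Evaluate a rule with the given genes knocked out (False), others True.

    The empty rule is active by convention (no gene requirement).
    """
    if rule is None or not rule.strip():
        return True
    return _Parser(_tokenize(rule), frozenset(deleted)).parse()


def rule_genes(rule: str) -> set[str]:
    """Return the set of gene ids referenced by a rule."""
    if rule is None or not rule.strip():
        return set()
    evaluate_gene_rule(rule)  # validate syntax
    return {t for t in _tokenize(rule) if t not in "()" and t.lower() not in _KEYWORDS}


def rule_is_valid(rule: str) -> bool:
    try:
        evaluate_gene_rule(rule)
        return True
    except GeneRuleError:
        return False
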