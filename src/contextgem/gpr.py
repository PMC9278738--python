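"""Gene-protein-reaction (GPR) rules: parsing, numeric scoring, knockouts.

A GPR rule is a Boolean expression over gene identifiers — e.g.
``(g1 and g2) or g3`` — stating which gene combinations produce an enzyme
catalysing the reaction.  AND typically groups complex subunits, OR groups
isozymes.  This module parses such rules into expression trees and
evaluates them in two modes:

* **Boolean**, for knockout propagation: a reaction is disabled by deleting
  gene ``g`` when its rule evaluates false with only ``g`` false.
* **Numeric**, to convert transcript activity scores (TAS) into reaction
  activity scores (RAS): AND becomes ``min`` (a complex is limited by its
  scarcest subunit) and OR becomes either ``max`` (the best-expressed
  isozyme carries the reaction) or ``sum`` (isozyme activities add up).

Evaluation is performed directly on the tree, without expansion to
disjunctive normal form; for ``min``/``max`` the two are equivalent, and
for ``sum`` the tree reading keeps each gene counted once per occurrence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "GPRRule",
    "GPRParseError",
    "parse_gpr",
    "reaction_score",
    "ras_from_tas",
    "core_set",
    "knockout_affected_reactions",
]

OR_FUNCTIONS: dict[str, Callable] = {"max": max, "sum": sum}
AND_FUNCTIONS: dict[str, Callable] = {"min": min, "max": max}


class GPRParseError(ValueError):
    """Raised for malformed rules; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class _Node:
    op: str  # "and" | "or" | "gene"
    children: tuple = ()
    gene: str | None = None


@dataclass(frozen=True)
class GPRRule:
    """A parsed GPR expression tree plus the original rule string."""

    root: _Node | None
    text: str

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def genes(self) -> frozenset[str]:
        if self.root is None:
            return frozenset()
        out: set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.op == "gene":
                out.add(node.gene)
            else:
                stack.extend(node.children)
        return frozenset(out)

    def evaluate_bool(self, active: Mapping[str, bool]) -> bool:
        """Boolean evaluation; genes missing from ``active`` count as active."""
        if self.root is None:
            raise ValueError("cannot evaluate an empty GPR rule")
        return self._eval_bool(self.root, active)

    def _eval_bool(self, node: _Node, active: Mapping[str, bool]) -> bool:
        if node.op == "gene":
            return bool(active.get(node.gene, True))
        vals = (self._eval_bool(c, active) for c in node.children)
        return all(vals) if node.op == "and" else any(vals)

    def evaluate_numeric(
        self,
        scores: Mapping[str, float],
        or_fn: str = "max",
        and_fn: str = "min",
        missing_value: float = 0.0,
    ) -> float:
        """Numeric evaluation with AND/OR replaced by aggregation functions."""
        if self.root is None:
            raise ValueError("cannot evaluate an empty GPR rule")
        if or_fn not in OR_FUNCTIONS:
            raise ValueError(f"or_fn must be one of {sorted(OR_FUNCTIONS)}, got {or_fn!r}")
        if and_fn not in AND_FUNCTIONS:
            raise ValueError(f"and_fn must be one of {sorted(AND_FUNCTIONS)}, got {and_fn!r}")
        return self._eval_num(self.root, scores, OR_FUNCTIONS[or_fn], AND_FUNCTIONS[and_fn], missing_value)

    def _eval_num(self, node, scores, or_f, and_f, missing) -> float:
        if node.op == "gene":
            if node.gene in scores:
                val = scores[node.gene]
                return missing if val is None or (isinstance(val, float) and np.isnan(val)) else float(val)
            return missing
        vals = [self._eval_num(c, scores, or_f, and_f, missing) for c in node.children]
        return float(and_f(vals) if node.op == "and" else or_f(vals))


_TOKEN = re.compile(r"\s*(?:(\()|(\))|([^\s()]+))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(text, pos)
        if m is None or m.end() == pos:
            raise GPRParseError(f"unexpected character {text[pos]!r}", pos)
        if m.group(1):
            tokens.append(("lparen", "(", m.start(1)))
        elif m.group(2):
            tokens.append(("rparen", ")", m.start(2)))
        else:
            word = m.group(3)
            low = word.lower()
            if low in ("and", "or"):
                tokens.append((low, word, m.start(3)))
            else:
                tokens.append(("gene", word, m.start(3)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str) -> GPRRule:
    """Parse a rule string into a :class:`GPRRule`.

    Grammar (AND binds tighter than OR, both case-insensitive)::

        expr    := term ("or" term)*
        term    := factor ("and" factor)*
        factor  := gene | "(" expr ")"

    An empty or whitespace-only string yields the empty rule.  Unbalanced
    parentheses or dangling operators raise :class:`GPRParseError` with the
    offending position.
    """
    text = rule or ""
    tokens = _tokenize(text)
    if not tokens:
        return GPRRule(root=None, text=text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None, len(text))

    def expr() -> _Node:
        nonlocal pos
        children = [term()]
        while peek()[0] == "or":
            pos += 1
            children.append(term())
        return children[0] if len(children) == 1 else _Node("or", tuple(children))

    def term() -> _Node:
        nonlocal pos
        children = [factor()]
        while peek()[0] == "and":
            pos += 1
            children.append(factor())
        return children[0] if len(children) == 1 else _Node("and", tuple(children))

    def factor() -> _Node:
        nonlocal pos
        kind, value, at = peek()
        if kind == "gene":
            pos += 1
            return _Node("gene", gene=value)
        if kind == "lparen":
            pos += 1
            node = expr()
            kind2, _, at2 = peek()
            if kind2 != "rparen":
                raise GPRParseError("unbalanced parentheses: missing ')'", at2)
            pos += 1
            return node
        raise GPRParseError(f"expected gene or '(', got {value!r}", at)

    root = expr()
    if pos != len(tokens):
        raise GPRParseError(f"unexpected token {tokens[pos][1]!r}", tokens[pos][2])
    return GPRRule(root=root, text=text)


# ---------------------------------------------------------------------------
# Reaction-level scoring
# ---------------------------------------------------------------------------

def reaction_score(
    rule: GPRRule,
    tas: Mapping[str, float],
    or_fn: str = "max",
    and_fn: str = "min",
    missing_value: float = 0.0,
) -> float:
    """RAS for one reaction: numeric evaluation of its GPR over gene TAS.

    Genes appearing in the rule but absent from ``tas`` are treated as
    expressed at the neutral score (default 0) and reported via a warning.
    """
    missing = rule.genes - set(tas)
    if missing:
        warnings.warn(f"genes without TAS treated as score {missing_value}: {sorted(missing)[:5]}")
    return rule.evaluate_numeric(tas, or_fn=or_fn, and_fn=and_fn, missing_value=missing_value)


def ras_from_tas(model, tas: Mapping[str, float], or_fn: str = "max", and_fn: str = "min"):
    """Per-reaction activity scores for a whole model.

    Returns ``(scores, has_gpr)`` — two dicts keyed by reaction id.
    Reactions without a GPR get the default score 0 and ``has_gpr`` False;
    they are excluded from FASTCORE cores and carry no weight in tINIT.
    """
    import pandas as pd

    scores: dict[str, float] = {}
    has_gpr: dict[str, bool] = {}
    known = set(tas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rxn in model.reactions:
            rule = parse_gpr(rxn.gene_reaction_rule)
            if rule.is_empty:
                scores[rxn.id] = 0.0
                has_gpr[rxn.id] = False
            else:
                scores[rxn.id] = reaction_score(rule, tas, or_fn=or_fn, and_fn=and_fn)
                has_gpr[rxn.id] = True
    unmapped = {g for r in model.reactions for g in parse_gpr(r.gene_reaction_rule).genes} - known
    if unmapped:
        warnings.warn(f"{len(unmapped)} model genes had no TAS and scored 0")
    return pd.Series(scores), pd.Series(has_gpr)


def core_set(ras: Mapping[str, float], has_gpr: Mapping[str, bool] | None = None) -> set[str]:
    """Core reactions for FASTCORE: strictly positive RAS, GPR-backed only."""
    return {
        r
        for r, score in dict(ras).items()
        if score > 0 and (has_gpr is None or has_gpr[r])
    }


def knockout_affected_reactions(gene: str, model) -> set[str]:
    """Reactions disabled when ``gene`` is deleted.

    A reaction is affected when its GPR evaluates false with every gene
    active except the deleted one.  Reactions without a GPR are never
    affected; an unknown gene yields the empty set with a warning (knockout
    screens include many non-metabolic genes).
    """
    model_genes = {g.id for g in model.genes}
    if gene not in model_genes:
        warnings.warn(f"gene {gene!r} not in model; no reactions affected")
        return set()
    affected = set()
    for rxn in model.reactions:
        rule = parse_gpr(rxn.gene_reaction_rule)
        if rule.is_empty or gene not in rule.genes:
            continue
        if not rule.evaluate_bool({gene: False}):
            affected.add(rxn.id)
    return affected
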