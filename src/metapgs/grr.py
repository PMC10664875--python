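"""Gene-reaction rules (GRRs) as n-ary AND/OR trees with a quantitative reading.

A GRR links a reaction to the genes encoding its enzyme(s).  AND joins
subunits of a complex, OR joins isozymes.  Under the quantitative
interpretation used throughout this package, a rule evaluated on relative
gene dosages in [0, 1] yields a multiplier delta in [0, 1]:

* AND -> minimum of the children (a complex is limited by its scarcest
  subunit),
* OR  -> sum of the children, clipped at 1 (isozymes contribute additively,
  but a mutant never exceeds the wild-type reference).

Clipping at each OR node is equivalent to a single final clip for any tree
whose leaves lie in [0, 1], and keeps the multiplier nondecreasing in every
dosage coordinate.
"""

from __future__ import annotations

import ast
import re
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping, Tuple, Union

from .exceptions import GeneLookupError, GRRParseError

__all__ = [
    "GRRTree",
    "GeneRef",
    "AndRule",
    "OrRule",
    "EmptyRule",
    "NO_GENE",
    "parse_grr",
    "evaluate_grr",
    "genes_in",
    "to_string",
]


@dataclass(frozen=True)
class GeneRef:
    """Leaf node referencing a single gene by id."""

    gene: str


@dataclass(frozen=True)
class AndRule:
    """Enzyme complex: all children required."""

    children: Tuple["GRRTree", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise GRRParseError("AND node requires at least 2 children")


@dataclass(frozen=True)
class OrRule:
    """Isozymes: any child suffices."""

    children: Tuple["GRRTree", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise GRRParseError("OR node requires at least 2 children")


@dataclass(frozen=True)
class EmptyRule:
    """Distinguished no-gene rule (spontaneous / orphan reaction)."""


GRRTree = Union[GeneRef, AndRule, OrRule, EmptyRule]

#: Shared instance of the no-gene rule.
NO_GENE = EmptyRule()


def parse_grr(rule: str) -> GRRTree:
    """Parse a GRR string such as ``"(a and b) or c"`` into a rule tree.

    AND binds tighter than OR; parentheses are respected; chains of the
    same operator are flattened into a single n-ary node.  The empty
    string yields :data:`NO_GENE`.

    Raises
    ------
    GRRParseError
        On unbalanced parentheses, dangling operators, or any other
        malformed rule.
    """
    if rule is None or not rule.strip():
        return NO_GENE
    # operators are case-insensitive
    rule = re.sub(r"\b(AND|OR)\b", lambda m: m.group(0).lower(), rule, flags=re.IGNORECASE)
    # Delegate tokenizing/parsing to cobrapy's GPR machinery (which handles
    # awkward gene identifiers), then convert its AST to our tree.
    from cobra.core.gene import GPR

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            gpr = GPR.from_string(rule)
    except (SyntaxWarning, SyntaxError, TypeError, ValueError) as exc:
        raise GRRParseError(f"malformed gene-reaction rule {rule!r}") from exc
    if gpr.body is None:
        return NO_GENE
    return _from_ast(gpr.body)


def _from_ast(node: ast.AST) -> GRRTree:
    if isinstance(node, ast.Name):
        return GeneRef(node.id)
    if isinstance(node, ast.BoolOp):
        cls = AndRule if isinstance(node.op, ast.And) else OrRule
        children: list[GRRTree] = []
        for child in (_from_ast(v) for v in node.values):
            # flatten same-operator nesting, e.g. "(a or b) or c"
            if isinstance(child, cls):
                children.extend(child.children)
            else:
                children.append(child)
        return cls(tuple(children))
    raise GRRParseError(f"unsupported GRR syntax node: {ast.dump(node)}")


def evaluate_grr(tree: GRRTree, dosages: Mapping[str, float]) -> float:
    """Evaluate a rule tree on relative gene dosages; returns delta in [0, 1].

    AND -> min of children, OR -> clipped sum, gene leaf -> its dosage,
    no-gene rule -> 1.  The result is finally clipped to [0, 1].
    """
    return min(1.0, max(0.0, _eval(tree, dosages)))


def _eval(tree: GRRTree, dosages: Mapping[str, float]) -> float:
    if isinstance(tree, EmptyRule):
        return 1.0
    if isinstance(tree, GeneRef):
        try:
            return float(dosages[tree.gene])
        except KeyError:
            raise GeneLookupError(tree.gene) from None
    values = [_eval(child, dosages) for child in tree.children]
    if isinstance(tree, AndRule):
        return min(values)
    return min(1.0, sum(values))


def genes_in(tree: GRRTree) -> frozenset:
    """Set of gene ids referenced anywhere in the rule."""
    return frozenset(_iter_genes(tree))


def _iter_genes(tree: GRRTree) -> Iterator[str]:
    if isinstance(tree, GeneRef):
        yield tree.gene
    elif isinstance(tree, (AndRule, OrRule)):
        for child in tree.children:
            yield from _iter_genes(child)


def to_string(tree: GRRTree) -> str:
    """Serialize a rule tree back to BiGG-style ``and``/``or`` notation."""
    return _fmt(tree, top=True)


def _fmt(tree: GRRTree, top: bool = False) -> str:
    if isinstance(tree, EmptyRule):
        return ""
    if isinstance(tree, GeneRef):
        return tree.gene
    op = " and " if isinstance(tree, AndRule) else " or "
    body = op.join(_fmt(c) for c in tree.children)
    return body if top else f"({body})"
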