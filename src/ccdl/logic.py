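"""Boolean normalization of a CCDL query into an executable expression tree.

The explicit logic layer is fixed by the language: inclusion criteria form
a CNF (AND of OR groups), exclusion criteria a DNF (OR of AND groups), and
the two are combined as inclusion AND NOT exclusion — the exclusion result
is subtracted from the inclusion result.  The implicit layer is applied at
the leaves: every criterion's term codes are expanded through the
terminology hierarchy (OR over the subtree), and all filters on one
criterion are conjoined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Union

from .errors import MissingLeafSet
from .model import (
    AttributeFilter,
    CCDLQuery,
    ContextCode,
    Criterion,
    CriterionKind,
    TermCode,
    TimeRestriction,
    classify_criterion,
)
from .terminology import CodeTree, expand_code


@dataclass(frozen=True)
class AtomicPredicate:
    """A criterion after implicit expansion: a duplicate-free ordered code
    set (OR across codes) plus the criterion's filters (AND across them)."""

    context: Optional[ContextCode]
    codeSet: tuple[TermCode, ...]
    kind: CriterionKind
    valueFilter: object = None
    attributeFilters: tuple[AttributeFilter, ...] = ()
    timeRestriction: Optional[TimeRestriction] = None

    def __post_init__(self) -> None:
        if not self.codeSet:
            raise ValueError("codeSet must be non-empty")
        if len({t.key for t in self.codeSet}) != len(self.codeSet):
            raise ValueError("codeSet must be duplicate-free")

    @property
    def code_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset(t.key for t in self.codeSet)


@dataclass(frozen=True)
class Leaf:
    predicate: AtomicPredicate


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("AND requires at least one child")


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("OR requires at least one child")


@dataclass(frozen=True)
class Not:
    child: "Node"


Node = Union[Leaf, And, Or, Not]
ExpressionTree = Node


def expand_criterion(c: Criterion, tree: CodeTree) -> AtomicPredicate:
    """Turn a criterion into an atomic predicate.

    The code set is the union of the hierarchy expansions of every term
    code (alternatives across terminologies are OR choices, as is the
    subtree of a parent code), duplicate-free in first-appearance order.
    All filters carry over unchanged.
    """
    seen: set[tuple[str, str]] = set()
    codes: list[TermCode] = []
    for t in c.termCodes:
        for e in expand_code(t, tree):
            if e.key not in seen:
                seen.add(e.key)
                codes.append(e)
    return AtomicPredicate(
        context=c.context,
        codeSet=tuple(codes),
        kind=classify_criterion(c),
        valueFilter=c.valueFilter,
        attributeFilters=c.attributeFilters,
        timeRestriction=c.timeRestriction,
    )


def _sort_key(node: Node) -> tuple[str, str]:
    if isinstance(node, Leaf):
        return node.predicate.codeSet[0].key
    if isinstance(node, Not):
        return _sort_key(node.child)
    return _sort_key(node.children[0])


def _group(nodes: list[Node], combiner) -> Node:
    nodes = sorted(nodes, key=_sort_key)
    return nodes[0] if len(nodes) == 1 else combiner(tuple(nodes))


def normalize_query(q: CCDLQuery, tree: CodeTree) -> ExpressionTree:
    """Build the executable boolean plan for a query.

    Shape: AND over inclusion groups of OR over group members; if exclusion
    criteria are present the root becomes AND(inclusion, NOT(OR over
    exclusion groups of AND over members)).  Singleton groups collapse to
    their only member, so NOT never occurs below the root combiner.
    Children are ordered lexicographically by their first code so the plan
    is deterministic for a given query and tree.
    """
    inclusion = _group(
        [_group([Leaf(expand_criterion(c, tree)) for c in group], Or) for group in q.inclusionCriteria],
        And,
    )
    if not q.exclusionCriteria:
        return inclusion
    exclusion = _group(
        [_group([Leaf(expand_criterion(c, tree)) for c in group], And) for group in q.exclusionCriteria],
        Or,
    )
    return And((inclusion, Not(exclusion)))


def iter_leaves(t: Node) -> list[Leaf]:
    """All leaves of a tree in deterministic left-to-right order."""
    out: list[Leaf] = []

    def visit(n: Node) -> None:
        if isinstance(n, Leaf):
            out.append(n)
        elif isinstance(n, Not):
            visit(n.child)
        else:
            for c in n.children:
                visit(c)

    visit(t)
    return out


def evaluate_tree(
    t: ExpressionTree,
    leaf_sets: dict[Leaf, frozenset[str] | set[str]],
    universe: set[str] | frozenset[str],
) -> set[str]:
    """Evaluate a plan over per-leaf patient-id sets.

    AND is intersection, OR is union, and NOT is complement relative to the
    universe — under the root AND this realizes the subtraction of the
    exclusion result from the inclusion result.
    """

    def visit(n: Node) -> set[str]:
        if isinstance(n, Leaf):
            if n not in leaf_sets:
                raise MissingLeafSet(f"no patient set for leaf with first code {n.predicate.codeSet[0]}")
            return set(leaf_sets[n])
        if isinstance(n, And):
            result = visit(n.children[0])
            for c in n.children[1:]:
                result &= visit(c)
            return result
        if isinstance(n, Or):
            result = visit(n.children[0])
            for c in n.children[1:]:
                result |= visit(c)
            return result
        return set(universe) - visit(n.child)

    return visit(t)


# ---------------------------------------------------------------------------
# Debug dumps
# ---------------------------------------------------------------------------


def _leaf_label(leaf: Leaf) -> str:
    p = leaf.predicate
    codes = ",".join(f"{t.system}|{t.code}" for t in p.codeSet[:3])
    if len(p.codeSet) > 3:
        codes += f",...(+{len(p.codeSet) - 3})"
    return f"{p.kind.value}[{codes}]"


def tree_to_text(t: Node, indent: int = 0) -> str:
    pad = "  " * indent
    if isinstance(t, Leaf):
        return f"{pad}LEAF {_leaf_label(t)}"
    if isinstance(t, Not):
        return f"{pad}NOT\n{tree_to_text(t.child, indent + 1)}"
    name = "AND" if isinstance(t, And) else "OR"
    lines = [f"{pad}{name}"] + [tree_to_text(c, indent + 1) for c in t.children]
    return "\n".join(lines)


def tree_to_data(t: Node) -> dict:
    if isinstance(t, Leaf):
        p = t.predicate
        return {
            "op": "leaf",
            "kind": p.kind.value,
            "context": f"{p.context.system}|{p.context.code}" if p.context else None,
            "codes": [f"{c.system}|{c.code}" for c in p.codeSet],
        }
    if isinstance(t, Not):
        return {"op": "not", "child": tree_to_data(t.child)}
    return {
        "op": "and" if isinstance(t, And) else "or",
        "children": [tree_to_data(c) for c in t.children],
    }


def tree_to_json(t: Node) -> str:
    return json.dumps(tree_to_data(t), indent=2) + "\n"
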