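"""Translation of an expression tree into a FHIR Search execution plan.

Each atomic predicate becomes one site-relative search URL; the boolean
combination is kept alongside as a combiner tree for client-side set
algebra (FHIR Search itself has no global negation).  OR across codes is
native FHIR OR: one token parameter with comma-joined ``system|code``
tokens.  AND across a criterion's filters is native FHIR AND: one
parameter per filter on the same URL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional
from urllib.parse import quote

from .errors import TranslationError, UnmappedReferenceFilter, UnsupportedAttribute
from .logic import And, ExpressionTree, Leaf, Node, Not, Or, iter_leaves
from .model import (
    AttributeFilter,
    ConceptFilter,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    ReferenceFilter,
    TermCode,
    Unit,
)
from .model import _decimal_str  # canonical decimal rendering shared with the model
from .terminology import CodeTree, MappingCatalog, MappingEntry, lookup_mapping

#: Code system implied for quantity units in search tokens.
UCUM_SYSTEM = "http://unitsofmeasure.org"

#: FHIR Search prefixes per comparator; equality has no prefix.
_PREFIX = {"eq": "", "ne": "ne", "lt": "lt", "le": "le", "gt": "gt", "ge": "ge"}

#: Characters left unencoded in query parameter values; matches how token
#: parameters with embedded system URIs are conventionally rendered.
_SAFE = ":/|,@$"


@dataclass(frozen=True)
class SearchQuery:
    """One site-relative FHIR search: resource path plus ordered parameters."""

    path: str
    params: tuple[tuple[str, str], ...]

    def render(self) -> str:
        if not self.params:
            return self.path
        joined = "&".join(f"{name}={quote(value, safe=_SAFE)}" for name, value in self.params)
        return f"{self.path}?{joined}"


def _token_list(codes) -> str:
    return ",".join(f"{t.system}|{t.code}" for t in codes)


def _quantity_token(prefix: str, value: Decimal, unit: Optional[Unit]) -> str:
    token = f"{prefix}{_decimal_str(value)}"
    if unit is not None:
        token += f"|{UCUM_SYSTEM}|{unit.code}"
    return token


def _value_params(param: str, f, *, where: str) -> list[tuple[str, str]]:
    if isinstance(f, (ConceptFilter, ReferenceFilter)):
        return [(param, _token_list(f.selectedConcepts))]
    if isinstance(f, QuantityComparatorFilter):
        return [(param, _quantity_token(_PREFIX[f.comparator.value], f.value, f.unit))]
    if isinstance(f, QuantityRangeFilter):
        return [
            (param, _quantity_token("ge", f.minValue, f.unit)),
            (param, _quantity_token("le", f.maxValue, f.unit)),
        ]
    raise UnsupportedAttribute(f"cannot translate filter {type(f).__name__} for {where}")


def predicate_to_search(
    p,
    catalog: MappingCatalog,
    tree: Optional[CodeTree] = None,
    ancestor_fallback: bool = False,
) -> SearchQuery:
    """Translate one atomic predicate into a single search URL.

    Canonical parameter order: term-code token, value filter, attribute
    filters (sorted by search parameter), time restriction.
    """
    entry: MappingEntry = lookup_mapping(p.context, p.codeSet[0], catalog, tree, ancestor_fallback)
    params: list[tuple[str, str]] = [(entry.termCodeSearchParam, _token_list(p.codeSet))]

    if p.valueFilter is not None:
        if entry.valueSearchParam is None:
            raise UnsupportedAttribute(
                f"mapping for {entry.termCode.system}|{entry.termCode.code} defines no value search parameter"
            )
        params.extend(_value_params(entry.valueSearchParam, p.valueFilter, where="value filter"))

    attr_params: list[tuple[str, str]] = []
    for af in p.attributeFilters:
        am = entry.attributeParams.get(af.attributeCode.key)
        if am is None:
            raise UnsupportedAttribute(
                f"attribute {af.attributeCode.system}|{af.attributeCode.code} not defined "
                f"in the mapping for {entry.termCode.system}|{entry.termCode.code}"
            )
        if isinstance(af.filter, ReferenceFilter) and am.typeHint != "reference":
            raise UnmappedReferenceFilter(
                f"attribute {af.attributeCode.system}|{af.attributeCode.code} carries a reference "
                "filter but the mapping declares no reference target"
            )
        attr_params.extend(_value_params(am.searchParam, af.filter, where="attribute filter"))
    params.extend(sorted(attr_params))

    if p.timeRestriction is not None:
        if entry.timeParam is None:
            raise UnsupportedAttribute(
                f"mapping for {entry.termCode.system}|{entry.termCode.code} defines no time search parameter"
            )
        tr = p.timeRestriction
        if tr.afterDate is not None:
            params.append((entry.timeParam, f"ge{tr.afterDate.isoformat()}"))
        if tr.beforeDate is not None:
            params.append((entry.timeParam, f"le{tr.beforeDate.isoformat()}"))

    return SearchQuery(path=entry.resourceType, params=tuple(params))


@dataclass
class FhirPlan:
    """A full execution plan: one search per leaf plus the combiner tree."""

    leaves: dict[str, SearchQuery]
    combiner: ExpressionTree
    leaf_ids: dict[Leaf, str] = field(default_factory=dict)

    def rendered(self) -> dict[str, str]:
        return {leaf_id: sq.render() for leaf_id, sq in self.leaves.items()}

    def _combiner_data(self, n: Node):
        if isinstance(n, Leaf):
            return {"op": "ref", "id": self.leaf_ids[n]}
        if isinstance(n, Not):
            return {"op": "not", "child": self._combiner_data(n.child)}
        return {
            "op": "and" if isinstance(n, And) else "or",
            "children": [self._combiner_data(c) for c in n.children],
        }

    def to_data(self) -> dict:
        return {"leaves": self.rendered(), "combiner": self._combiner_data(self.combiner)}


def plan_query(
    t: ExpressionTree,
    catalog: MappingCatalog,
    tree: Optional[CodeTree] = None,
    ancestor_fallback: bool = False,
) -> FhirPlan:
    """Translate a whole plan; per-leaf failures are aggregated into one
    :class:`TranslationError` carrying the failing leaf ids."""
    leaf_ids: dict[Leaf, str] = {}
    leaves: dict[str, SearchQuery] = {}
    failures: list[tuple[str, Exception]] = []
    for leaf in iter_leaves(t):
        if leaf in leaf_ids:
            continue
        leaf_id = f"c{len(leaf_ids) + 1}"
        leaf_ids[leaf] = leaf_id
        try:
            leaves[leaf_id] = predicate_to_search(leaf.predicate, catalog, tree, ancestor_fallback)
        except Exception as exc:  # noqa: BLE001 - aggregated and re-raised
            failures.append((leaf_id, exc))
    if failures:
        raise TranslationError(failures)
    return FhirPlan(leaves=leaves, combiner=t, leaf_ids=leaf_ids)
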