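"""Independent brute-force reference for feasibility-query semantics.

Deliberately re-implements the raw CNF/DNF/AND-NOT definition per patient
— no expression trees, no expand_code, no event_matches — so it can serve
as an oracle for the engine.  Written against the language definition
only: a patient is in the cohort iff every inclusion group contains at
least one satisfied criterion and no exclusion group has all its criteria
satisfied.
"""

from __future__ import annotations

from ccdl.evaluator import PatientRecord, Quantity
from ccdl.model import (
    CCDLQuery,
    ConceptFilter,
    Criterion,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    ReferenceFilter,
    TermCode,
)
from ccdl.terminology import CodeTree, CodeTreeNode


def subtree_keys(tree: CodeTree, t: TermCode) -> set[tuple[str, str]]:
    """(system, code) keys of t plus all its descendants, by direct walk of
    the forest; {t} when absent."""

    def collect(node: CodeTreeNode) -> set[tuple[str, str]]:
        keys = {node.termCode.key}
        for child in node.children:
            keys |= collect(child)
        return keys

    def find(node: CodeTreeNode):
        if node.termCode.key == t.key:
            return node
        for child in node.children:
            hit = find(child)
            if hit is not None:
                return hit
        return None

    for root in tree.roots:
        hit = find(root)
        if hit is not None:
            return collect(hit)
    return {t.key}


def _units_equal(a, b) -> bool:
    return (a.code if a is not None else None) == (b.code if b is not None else None)


def _value_satisfies(f, observed) -> bool:
    if isinstance(f, (ConceptFilter, ReferenceFilter)):
        if not isinstance(observed, TermCode):
            return False
        return any(observed.key == c.key for c in f.selectedConcepts)
    if isinstance(f, QuantityComparatorFilter):
        if not isinstance(observed, Quantity) or not _units_equal(f.unit, observed.unit):
            return False
        c = f.comparator.value
        if c == "eq":
            return observed.value == f.value
        if c == "ne":
            return observed.value != f.value
        if c == "lt":
            return observed.value < f.value
        if c == "le":
            return observed.value <= f.value
        if c == "gt":
            return observed.value > f.value
        return observed.value >= f.value
    if isinstance(f, QuantityRangeFilter):
        if not isinstance(observed, Quantity) or not _units_equal(f.unit, observed.unit):
            return False
        return f.minValue <= observed.value <= f.maxValue
    raise TypeError(type(f))


def criterion_satisfied(criterion: Criterion, patient: PatientRecord, tree: CodeTree) -> bool:
    keys: set[tuple[str, str]] = set()
    for t in criterion.termCodes:
        keys |= subtree_keys(tree, t)
    for e in patient.events:
        if criterion.context is not None and e.context.key != criterion.context.key:
            continue
        if e.code.key not in keys:
            continue
        if criterion.valueFilter is not None and not _value_satisfies(criterion.valueFilter, e.value):
            continue
        if any(
            not _value_satisfies(af.filter, e.attributes.get(af.attributeCode.key))
            for af in criterion.attributeFilters
        ):
            continue
        tr = criterion.timeRestriction
        if tr is not None:
            if e.date is None:
                continue
            if tr.afterDate is not None and e.date < tr.afterDate:
                continue
            if tr.beforeDate is not None and e.date > tr.beforeDate:
                continue
        return True
    return False


def brute_force_cohort(q: CCDLQuery, dataset: list[PatientRecord], tree: CodeTree) -> set[str]:
    """Per-patient evaluation of the raw language definition."""
    cohort: set[str] = set()
    for patient in dataset:
        included = all(
            any(criterion_satisfied(c, patient, tree) for c in group) for group in q.inclusionCriteria
        )
        excluded = bool(q.exclusionCriteria) and any(
            all(criterion_satisfied(c, patient, tree) for c in group) for group in q.exclusionCriteria
        )
        if included and not excluded:
            cohort.add(patient.patientId)
    return cohort
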