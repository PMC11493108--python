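"""Reference in-memory execution of feasibility queries.

This is the ground-truth semantics for both translators: a synthetic
patient store of clinical events, an event matcher implementing the
criterion semantics (all filters on one criterion must hold on the same
event), and a query runner that combines per-criterion patient sets with
the CNF/DNF/AND-NOT set algebra.  The headline output is the cohort size.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from datetime import date
from decimal import Decimal
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import MalformedJson, SchemaViolation
from .logic import AtomicPredicate, Leaf, evaluate_tree, iter_leaves, normalize_query
from .model import (
    CCDLQuery,
    ConceptFilter,
    ContextCode,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    ReferenceFilter,
    TermCode,
    Unit,
    emit_compact,
)
from .terminology import CodeTree


@dataclass(frozen=True)
class Quantity:
    value: Decimal
    unit: Optional[Unit] = None


EventValue = Union[Quantity, TermCode]


@dataclass
class ClinicalEvent:
    """One clinical fact about a patient: a coded concept in a context,
    optionally with a numeric or concept value, coded attributes, and a
    calendar date."""

    context: ContextCode
    code: TermCode
    value: Optional[EventValue] = None
    attributes: dict[tuple[str, str], EventValue] = field(default_factory=dict)
    date: Optional[date] = None


@dataclass
class PatientRecord:
    patientId: str
    events: list[ClinicalEvent] = field(default_factory=list)


Dataset = list[PatientRecord]


@dataclass(frozen=True)
class FeasibilityResult:
    """Cohort size plus the underlying patient ids (count is the headline)."""

    patientIds: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.patientIds)


# ---------------------------------------------------------------------------
# Matching semantics
# ---------------------------------------------------------------------------


def _units_match(a: Optional[Unit], b: Optional[Unit]) -> bool:
    # Exact UCUM code equality; no unit conversion — a mismatch is a
    # non-match, never an equivalence.
    if a is None and b is None:
        return True
    if a is None or b is None:
        return False
    return a.code == b.code


def _compare(op: str, left: Decimal, right: Decimal) -> bool:
    if op == "eq":
        return left == right
    if op == "ne":
        return left != right
    if op == "lt":
        return left < right
    if op == "le":
        return left <= right
    if op == "gt":
        return left > right
    return left >= right


def _filter_matches(f, observed: Optional[EventValue]) -> bool:
    if isinstance(f, (ConceptFilter, ReferenceFilter)):
        return isinstance(observed, TermCode) and observed in f.selectedConcepts
    if isinstance(f, QuantityComparatorFilter):
        # Absent or non-numeric values never match — including for `ne`
        # (no negation-as-failure on missing data).
        if not isinstance(observed, Quantity):
            return False
        if not _units_match(f.unit, observed.unit):
            return False
        return _compare(f.comparator.value, observed.value, f.value)
    if isinstance(f, QuantityRangeFilter):
        if not isinstance(observed, Quantity):
            return False
        if not _units_match(f.unit, observed.unit):
            return False
        return f.minValue <= observed.value <= f.maxValue
    raise TypeError(f"unknown filter {type(f).__name__}")  # pragma: no cover


def event_matches(p: AtomicPredicate, e: ClinicalEvent) -> bool:
    """Whether one event satisfies every part of a predicate.

    All filters are conjoined and must hold on this same event; date
    bounds are inclusive; an absent predicate context matches any event
    context.
    """
    if p.context is not None and (e.context is None or e.context.key != p.context.key):
        return False
    if e.code.key not in p.code_keys:
        return False
    if p.valueFilter is not None and not _filter_matches(p.valueFilter, e.value):
        return False
    for af in p.attributeFilters:
        if not _filter_matches(af.filter, e.attributes.get(af.attributeCode.key)):
            return False
    tr = p.timeRestriction
    if tr is not None:
        if e.date is None:
            return False
        if tr.afterDate is not None and e.date < tr.afterDate:
            return False
        if tr.beforeDate is not None and e.date > tr.beforeDate:
            return False
    return True


def evaluate_criterion_set(p: AtomicPredicate, dataset: Dataset) -> set[str]:
    """Patients with at least one event matching the predicate."""
    return {
        patient.patientId
        for patient in dataset
        if any(event_matches(p, e) for e in patient.events)
    }


def run_query(q: CCDLQuery, dataset: Dataset, tree: CodeTree) -> FeasibilityResult:
    """Compute the feasibility count of a query over a dataset."""
    plan = normalize_query(q, tree)
    leaf_sets: dict[Leaf, set[str]] = {}
    for leaf in iter_leaves(plan):
        if leaf not in leaf_sets:
            leaf_sets[leaf] = evaluate_criterion_set(leaf.predicate, dataset)
    universe = {patient.patientId for patient in dataset}
    return FeasibilityResult(patientIds=frozenset(evaluate_tree(plan, leaf_sets, universe)))


# ---------------------------------------------------------------------------
# Dataset interchange (JSON lines, one patient record per line)
# ---------------------------------------------------------------------------


class _UnitModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    code: str
    display: Optional[str] = None


class _CodeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    system: str
    code: str
    version: Optional[str] = None
    display: Optional[str] = None


class _ValueModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    value: Optional[Decimal] = None
    unit: Optional[_UnitModel] = None
    concept: Optional[_CodeModel] = None

    def build(self) -> EventValue:
        if (self.concept is None) == (self.value is None):
            raise SchemaViolation("event value must carry exactly one of a numeric value or a concept")
        if self.concept is not None:
            return TermCode(**self.concept.model_dump())
        return Quantity(value=self.value, unit=Unit(**self.unit.model_dump()) if self.unit else None)


class _EventModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    context: _CodeModel
    code: _CodeModel
    value: Optional[_ValueModel] = None
    attributes: dict[str, _ValueModel] = {}
    date: Optional[_dt.date] = None


class _PatientModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    patientId: str
    events: list[_EventModel] = []


def _attr_key(raw: str) -> tuple[str, str]:
    system, sep, code = raw.partition("|")
    if not sep or not system or not code:
        raise SchemaViolation(f"attribute key {raw!r} must look like 'system|code'")
    return (system, code)


def load_dataset(jsonl_text: str) -> Dataset:
    """Read a dataset from JSON-lines text with strict validation; patient
    ids must be unique."""
    patients: Dataset = []
    seen: set[str] = set()
    for lineno, line in enumerate(jsonl_text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            data = json.loads(line, parse_float=Decimal)
        except json.JSONDecodeError as exc:
            raise MalformedJson(f"line {lineno}: {exc}") from exc
        try:
            pm = _PatientModel.model_validate(data)
        except ValidationError as exc:
            raise SchemaViolation(f"line {lineno}: {exc.errors()[0]['msg']}") from exc
        if pm.patientId in seen:
            raise SchemaViolation(f"line {lineno}: duplicate patientId {pm.patientId!r}")
        seen.add(pm.patientId)
        events = []
        for em in pm.events:
            events.append(
                ClinicalEvent(
                    context=ContextCode(**em.context.model_dump()),
                    code=TermCode(**em.code.model_dump()),
                    value=em.value.build() if em.value is not None else None,
                    attributes={_attr_key(k): v.build() for k, v in em.attributes.items()},
                    date=em.date,
                )
            )
        patients.append(PatientRecord(patientId=pm.patientId, events=events))
    return patients


def _code_data(t: TermCode) -> dict:
    out = {"system": t.system, "code": t.code}
    if t.display is not None:
        out["display"] = t.display
    return out


def _value_data(v: EventValue) -> dict:
    if isinstance(v, TermCode):
        return {"concept": _code_data(v)}
    out: dict = {"value": v.value}
    if v.unit is not None:
        out["unit"] = {"code": v.unit.code}
    return out


def dump_dataset(dataset: Dataset) -> str:
    lines = []
    for patient in dataset:
        events = []
        for e in patient.events:
            ev: dict = {"context": _code_data(e.context), "code": _code_data(e.code)}
            if e.value is not None:
                ev["value"] = _value_data(e.value)
            if e.attributes:
                ev["attributes"] = {f"{k[0]}|{k[1]}": _value_data(v) for k, v in sorted(e.attributes.items())}
            if e.date is not None:
                ev["date"] = e.date.isoformat()
            events.append(ev)
        lines.append(emit_compact({"patientId": patient.patientId, "events": events}))
    return "\n".join(lines) + ("\n" if lines else "")
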