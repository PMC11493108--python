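"""CCDL document model: types, parsing, validation, canonical serialization.

The Clinical Cohort Definition Language (CCDL) expresses a feasibility
query as a JSON document: inclusion criteria in conjunctive normal form
(outer list = AND, inner lists = OR groups), optional exclusion criteria in
disjunctive normal form (outer list = OR, inner lists = AND groups), and no
negation anywhere inside either structure.  The atomic unit is the
criterion: a clinical concept identified by one or more (system, code)
term codes, optionally disambiguated by a context code, and restricted by
at most one value filter, any number of attribute filters, and at most one
time restriction.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from datetime import date
from decimal import Decimal, InvalidOperation
from typing import Annotated, Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .errors import InvariantViolation, MalformedJson, SchemaViolation, UnsupportedVersion

#: The single CCDL syntax version this implementation accepts.
SYNTAX_VERSION = "1.0"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


# ---------------------------------------------------------------------------
# Terminology primitives
# ---------------------------------------------------------------------------


class TermCode(_Strict):
    """A clinical concept identified by a (code system, code) tuple.

    ``display`` and ``version`` are cosmetic: equality and hashing consider
    only the (system, code) pair, so two term codes naming the same concept
    compare equal regardless of annotation.
    """

    system: str
    code: str
    version: Optional[str] = None
    display: Optional[str] = None

    @field_validator("system", "code")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("system and code must be non-empty")
        return v

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermCode):
            return NotImplemented
        return (self.system, self.code) == (other.system, other.code)

    def __hash__(self) -> int:
        return hash((self.system, self.code))

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.code)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.system}|{self.code}"


class ContextCode(TermCode):
    """An extra term code disambiguating a concept's role (e.g. myocardial
    infarction as a condition versus as a cause of death)."""


class Unit(_Strict):
    """A UCUM-coded unit of measure."""

    code: str
    display: Optional[str] = None

    @field_validator("code")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("unit code must be non-empty")
        return v


class Comparator(str, enum.Enum):
    EQ = "eq"
    NE = "ne"
    LT = "lt"
    LE = "le"
    GT = "gt"
    GE = "ge"


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


class ConceptFilter(_Strict):
    """Value-set restriction: the observed concept must be one of the
    selected concepts (OR across the selection)."""

    type: Literal["concept"] = "concept"
    selectedConcepts: tuple[TermCode, ...]

    @field_validator("selectedConcepts")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("selectedConcepts must be non-empty")
        return v


class QuantityComparatorFilter(_Strict):
    """Comparative numeric restriction, e.g. hemoglobin < 12 g/dL."""

    type: Literal["quantity-comparator"] = "quantity-comparator"
    comparator: Comparator
    value: Decimal
    unit: Optional[Unit] = None


class QuantityRangeFilter(_Strict):
    """Inclusive numeric range restriction, e.g. hemoglobin in [10, 12] g/dL."""

    type: Literal["quantity-range"] = "quantity-range"
    minValue: Decimal
    maxValue: Decimal
    unit: Optional[Unit] = None

    @model_validator(mode="after")
    def _ordered(self):
        if self.minValue > self.maxValue:
            raise ValueError("minValue must be <= maxValue")
        return self


class ReferenceFilter(_Strict):
    """Attribute filter variant pointing at other coded entities.

    Structurally preserved by the model; the evaluator treats it like a
    concept filter and translators require an explicit reference target in
    the mapping.
    """

    type: Literal["reference"] = "reference"
    selectedConcepts: tuple[TermCode, ...]

    @field_validator("selectedConcepts")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("selectedConcepts must be non-empty")
        return v


ValueFilter = Annotated[
    Union[ConceptFilter, QuantityComparatorFilter, QuantityRangeFilter],
    Field(discriminator="type"),
]

AttributeFilterVariant = Annotated[
    Union[ConceptFilter, QuantityComparatorFilter, QuantityRangeFilter, ReferenceFilter],
    Field(discriminator="type"),
]

_FILTER_TAGS = {"concept", "quantity-comparator", "quantity-range", "reference"}


class AttributeFilter(_Strict):
    """A restriction on a secondary property of the matched object,
    e.g. body site = skin for a tissue specimen.

    The JSON form is flat (``attributeCode`` next to the filter's own
    members); the model keeps the filter as a nested tagged union.
    """

    attributeCode: TermCode
    filter: AttributeFilterVariant

    @model_validator(mode="before")
    @classmethod
    def _flatten(cls, data):
        if isinstance(data, dict) and "filter" not in data:
            data = dict(data)
            return {
                "attributeCode": data.pop("attributeCode", None),
                "filter": data,
            }
        return data


class TimeRestriction(_Strict):
    """Inclusive calendar-date window a criterion must fall into."""

    afterDate: Optional[date] = None
    beforeDate: Optional[date] = None

    @model_validator(mode="after")
    def _check(self):
        if self.afterDate is None and self.beforeDate is None:
            raise ValueError("at least one of afterDate/beforeDate must be present")
        if self.afterDate is not None and self.beforeDate is not None and self.afterDate > self.beforeDate:
            raise ValueError("afterDate must be <= beforeDate")
        return self


# ---------------------------------------------------------------------------
# Criterion and query
# ---------------------------------------------------------------------------


class Criterion(_Strict):
    """Atomic query unit.

    ``termCodes`` holds semantically equivalent alternatives across
    terminologies (OR across entries); all filters on one criterion combine
    with AND.
    """

    context: Optional[ContextCode] = None
    termCodes: tuple[TermCode, ...]
    valueFilter: Optional[ValueFilter] = None
    attributeFilters: tuple[AttributeFilter, ...] = ()
    timeRestriction: Optional[TimeRestriction] = None

    @field_validator("termCodes")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("termCodes must be non-empty")
        return v

    @model_validator(mode="after")
    def _distinct_attributes(self):
        seen = set()
        for af in self.attributeFilters:
            if af.attributeCode.key in seen:
                raise ValueError(f"duplicate attributeCode {af.attributeCode.system}|{af.attributeCode.code}")
            seen.add(af.attributeCode.key)
        return self


class CriterionKind(enum.Enum):
    EXIST = "exist"
    QUANTITY_COMPARATOR = "quantity-comparator"
    QUANTITY_RANGE = "quantity-range"
    VALUE_SET = "value-set"


class CCDLQuery(_Strict):
    """A versioned feasibility query document.

    ``inclusionCriteria`` is a CNF without negation: the outer list is a
    conjunction of OR groups.  ``exclusionCriteria`` is a DNF without
    negation: the outer list is a disjunction of AND groups.  The query
    result is the inclusion result minus the exclusion result.
    """

    version: str
    display: Optional[str] = None
    inclusionCriteria: tuple[tuple[Criterion, ...], ...]
    exclusionCriteria: Optional[tuple[tuple[Criterion, ...], ...]] = None

    @field_validator("version")
    @classmethod
    def _version_non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("version must be non-empty")
        return v

    @field_validator("inclusionCriteria")
    @classmethod
    def _inclusion_shape(cls, v):
        if not v:
            raise ValueError("inclusionCriteria must be non-empty")
        for i, group in enumerate(v):
            if not group:
                raise ValueError(f"inclusion group {i} is empty")
        return v

    @field_validator("exclusionCriteria")
    @classmethod
    def _exclusion_shape(cls, v):
        if v is None:
            return v
        for i, group in enumerate(v):
            if not group:
                raise ValueError(f"exclusion group {i} is empty")
        return v


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "query": {"version", "display", "inclusionCriteria", "exclusionCriteria"},
    "criterion": {"context", "termCodes", "valueFilter", "attributeFilters", "timeRestriction"},
    "termCode": {"system", "code", "version", "display"},
    "unit": {"code", "display"},
    "timeRestriction": {"afterDate", "beforeDate"},
    "valueFilter": {
        "concept": {"type", "selectedConcepts"},
        "quantity-comparator": {"type", "comparator", "value", "unit"},
        "quantity-range": {"type", "minValue", "maxValue", "unit"},
        "reference": {"type", "selectedConcepts"},
    },
}


def _strip_unknown(data, shape: str, path: str, warnings: list[str]):
    """Recursively drop members not in the accepted dialect (lenient mode)."""
    if not isinstance(data, dict):
        return data
    if shape in ("valueFilter", "attributeFilter"):
        tag = data.get("type")
        allowed = set(_ALLOWED_KEYS["valueFilter"].get(tag, {"type"}))
        if shape == "attributeFilter":
            allowed = allowed | {"attributeCode"}
    else:
        allowed = _ALLOWED_KEYS[shape]
    out = {}
    for k, v in data.items():
        if k not in allowed:
            warnings.append(f"{path}/{k}: unknown member ignored")
            continue
        out[k] = v
    if shape == "query":
        for fld in ("inclusionCriteria", "exclusionCriteria"):
            if isinstance(out.get(fld), list):
                out[fld] = [
                    [
                        _strip_unknown(c, "criterion", f"{path}/{fld}/{i}/{j}", warnings)
                        if isinstance(c, dict)
                        else c
                        for j, c in enumerate(group)
                    ]
                    if isinstance(group, list)
                    else group
                    for i, group in enumerate(out[fld])
                ]
    elif shape == "criterion":
        if isinstance(out.get("context"), dict):
            out["context"] = _strip_unknown(out["context"], "termCode", f"{path}/context", warnings)
        if isinstance(out.get("termCodes"), list):
            out["termCodes"] = [
                _strip_unknown(t, "termCode", f"{path}/termCodes/{i}", warnings) if isinstance(t, dict) else t
                for i, t in enumerate(out["termCodes"])
            ]
        if isinstance(out.get("valueFilter"), dict):
            out["valueFilter"] = _strip_unknown(out["valueFilter"], "valueFilter", f"{path}/valueFilter", warnings)
        if isinstance(out.get("attributeFilters"), list):
            out["attributeFilters"] = [
                _strip_unknown(a, "attributeFilter", f"{path}/attributeFilters/{i}", warnings)
                if isinstance(a, dict)
                else a
                for i, a in enumerate(out["attributeFilters"])
            ]
        if isinstance(out.get("timeRestriction"), dict):
            out["timeRestriction"] = _strip_unknown(
                out["timeRestriction"], "timeRestriction", f"{path}/timeRestriction", warnings
            )
    elif shape in ("valueFilter", "attributeFilter"):
        if isinstance(out.get("unit"), dict):
            out["unit"] = _strip_unknown(out["unit"], "unit", f"{path}/unit", warnings)
        if isinstance(out.get("selectedConcepts"), list):
            out["selectedConcepts"] = [
                _strip_unknown(t, "termCode", f"{path}/selectedConcepts/{i}", warnings) if isinstance(t, dict) else t
                for i, t in enumerate(out["selectedConcepts"])
            ]
        if isinstance(out.get("attributeCode"), dict):
            out["attributeCode"] = _strip_unknown(out["attributeCode"], "termCode", f"{path}/attributeCode", warnings)
    return out


def _loc_to_pointer(loc: tuple) -> str:
    parts = []
    for seg in loc:
        if isinstance(seg, str) and seg in _FILTER_TAGS:
            continue  # discriminated-union tag, not a JSON member
        if seg == "filter":
            continue  # internal nesting of the flat attribute-filter JSON
        parts.append(str(seg))
    return "/" + "/".join(parts) if parts else ""


_INVARIANT_ERROR_TYPES = {"value_error", "assertion_error"}


def _raise_from_validation_error(exc: ValidationError) -> None:
    schema_errors, invariant_errors = [], []
    for err in exc.errors():
        pointer = _loc_to_pointer(err["loc"])
        msg = err["msg"]
        if err["type"] in _INVARIANT_ERROR_TYPES:
            invariant_errors.append((pointer, msg.removeprefix("Value error, ")))
        else:
            if err["type"] == "extra_forbidden":
                msg = "unknown member"
            schema_errors.append((pointer, msg))
    if schema_errors:
        pointer, msg = schema_errors[0]
        raise SchemaViolation(msg, pointer) from exc
    pointer, msg = invariant_errors[0]
    raise InvariantViolation(msg, pointer) from exc


def parse_query(json_text: str, *, strict: bool = True, warnings: Optional[list[str]] = None) -> CCDLQuery:
    """Parse CCDL JSON text into a validated :class:`CCDLQuery`.

    In strict mode (default) unknown JSON members raise
    :class:`SchemaViolation`; in lenient mode they are dropped and recorded
    in ``warnings`` (if a list is supplied).  Numeric literals are read as
    exact decimals so serialization round-trips byte-identically.
    """
    try:
        data = json.loads(json_text, parse_float=Decimal)
    except (json.JSONDecodeError, InvalidOperation) as exc:
        raise MalformedJson(str(exc)) from exc
    if not isinstance(data, dict):
        raise SchemaViolation("document root must be a JSON object")
    if "version" in data and isinstance(data["version"], str) and data["version"] and data["version"] != SYNTAX_VERSION:
        raise UnsupportedVersion(
            f"query declares syntax version {data['version']!r}; this implementation accepts {SYNTAX_VERSION!r}"
        )
    if not strict:
        data = _strip_unknown(data, "query", "", warnings if warnings is not None else [])
    try:
        return CCDLQuery.model_validate(data)
    except ValidationError as exc:
        _raise_from_validation_error(exc)
        raise AssertionError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# Canonical serialization
# ---------------------------------------------------------------------------


def _decimal_str(d: Decimal) -> str:
    """Canonical plain-notation rendering of a decimal (no exponent, no
    trailing fractional zeros)."""
    s = format(d.normalize(), "f")
    return s


def _term_code_data(t: TermCode) -> dict:
    out = {"system": t.system, "code": t.code}
    if t.version is not None:
        out["version"] = t.version
    if t.display is not None:
        out["display"] = t.display
    return out


def _unit_data(u: Unit) -> dict:
    out = {"code": u.code}
    if u.display is not None:
        out["display"] = u.display
    return out


def _filter_data(f) -> dict:
    if isinstance(f, (ConceptFilter, ReferenceFilter)):
        return {"type": f.type, "selectedConcepts": [_term_code_data(t) for t in f.selectedConcepts]}
    if isinstance(f, QuantityComparatorFilter):
        out = {"type": f.type, "comparator": f.comparator.value, "value": f.value}
        if f.unit is not None:
            out["unit"] = _unit_data(f.unit)
        return out
    if isinstance(f, QuantityRangeFilter):
        out = {"type": f.type, "minValue": f.minValue, "maxValue": f.maxValue}
        if f.unit is not None:
            out["unit"] = _unit_data(f.unit)
        return out
    raise TypeError(f"unknown filter {f!r}")  # pragma: no cover


def _criterion_data(c: Criterion) -> dict:
    out: dict = {}
    if c.context is not None:
        out["context"] = _term_code_data(c.context)
    out["termCodes"] = [_term_code_data(t) for t in c.termCodes]
    if c.valueFilter is not None:
        out["valueFilter"] = _filter_data(c.valueFilter)
    if c.attributeFilters:
        out["attributeFilters"] = [
            {"attributeCode": _term_code_data(af.attributeCode), **_filter_data(af.filter)}
            for af in c.attributeFilters
        ]
    if c.timeRestriction is not None:
        tr = {}
        if c.timeRestriction.afterDate is not None:
            tr["afterDate"] = c.timeRestriction.afterDate.isoformat()
        if c.timeRestriction.beforeDate is not None:
            tr["beforeDate"] = c.timeRestriction.beforeDate.isoformat()
        out["timeRestriction"] = tr
    return out


def query_to_data(q: CCDLQuery) -> dict:
    """Plain-Python structure of a query in canonical member order
    (decimal values kept exact)."""
    out: dict = {"version": q.version}
    if q.display is not None:
        out["display"] = q.display
    out["inclusionCriteria"] = [[_criterion_data(c) for c in group] for group in q.inclusionCriteria]
    if q.exclusionCriteria is not None:
        out["exclusionCriteria"] = [[_criterion_data(c) for c in group] for group in q.exclusionCriteria]
    return out


def _emit(obj, indent: int) -> str:
    pad = "  " * indent
    child_pad = "  " * (indent + 1)
    if isinstance(obj, dict):
        if not obj:
            return "{}"
        items = [f'{child_pad}{json.dumps(k)}: {_emit(v, indent + 1)}' for k, v in obj.items()]
        return "{\n" + ",\n".join(items) + "\n" + pad + "}"
    if isinstance(obj, list):
        if not obj:
            return "[]"
        items = [f"{child_pad}{_emit(v, indent + 1)}" for v in obj]
        return "[\n" + ",\n".join(items) + "\n" + pad + "]"
    if isinstance(obj, Decimal):
        return _decimal_str(obj)
    if isinstance(obj, bool) or obj is None or isinstance(obj, (int, float, str)):
        return json.dumps(obj)
    raise TypeError(f"cannot serialize {type(obj)}")  # pragma: no cover


def emit_compact(obj) -> str:
    """Single-line deterministic JSON with exact decimal literals (used for
    JSON-lines artifacts)."""
    if isinstance(obj, dict):
        return "{" + ",".join(f"{json.dumps(k)}:{emit_compact(v)}" for k, v in obj.items()) + "}"
    if isinstance(obj, list):
        return "[" + ",".join(emit_compact(v) for v in obj) + "]"
    if isinstance(obj, Decimal):
        return _decimal_str(obj)
    return json.dumps(obj)


def serialize_query(q: CCDLQuery) -> str:
    """Emit canonical, byte-deterministic CCDL JSON for a valid query.

    Canonicality: fixed member order, two-space indentation, plain decimal
    notation, optional members omitted when absent.  ``parse_query`` of the
    output reproduces ``q``; re-serializing is a byte-level fixpoint.
    """
    violations = validate_query(q)
    if violations:
        v = violations[0]
        raise InvariantViolation(v.message, v.path)
    return _emit(query_to_data(q), 0) + "\n"


# ---------------------------------------------------------------------------
# Classification and validation
# ---------------------------------------------------------------------------


def classify_criterion(c: Criterion) -> CriterionKind:
    """Assign one of the four base criterion types.

    Attribute filters and time restrictions do not affect the kind; only
    the value filter variant does.
    """
    if c.valueFilter is None:
        return CriterionKind.EXIST
    if isinstance(c.valueFilter, ConceptFilter):
        return CriterionKind.VALUE_SET
    if isinstance(c.valueFilter, QuantityComparatorFilter):
        return CriterionKind.QUANTITY_COMPARATOR
    return CriterionKind.QUANTITY_RANGE


@dataclass(frozen=True)
class Violation:
    """A single invariant violation, reported as data rather than raised."""

    path: str
    rule: str
    message: str


def _check_term_code(t, path: str, out: list[Violation]) -> None:
    if not getattr(t, "system", None) or not getattr(t, "code", None):
        out.append(Violation(path, "term-code-non-empty", "system and code must be non-empty"))


def _check_filter(f, path: str, out: list[Violation]) -> None:
    if isinstance(f, (ConceptFilter, ReferenceFilter)):
        if not f.selectedConcepts:
            out.append(Violation(f"{path}/selectedConcepts", "concepts-non-empty", "selectedConcepts must be non-empty"))
        for i, t in enumerate(f.selectedConcepts):
            _check_term_code(t, f"{path}/selectedConcepts/{i}", out)
    elif isinstance(f, QuantityRangeFilter):
        if f.minValue > f.maxValue:
            out.append(Violation(path, "range-ordered", "minValue must be <= maxValue"))
    if getattr(f, "unit", None) is not None and not f.unit.code:
        out.append(Violation(f"{path}/unit", "unit-non-empty", "unit code must be non-empty"))


def _check_criterion(c: Criterion, path: str, out: list[Violation]) -> None:
    if c.context is not None:
        _check_term_code(c.context, f"{path}/context", out)
    if not c.termCodes:
        out.append(Violation(f"{path}/termCodes", "term-codes-non-empty", "termCodes must be non-empty"))
    for i, t in enumerate(c.termCodes):
        _check_term_code(t, f"{path}/termCodes/{i}", out)
    if c.valueFilter is not None:
        _check_filter(c.valueFilter, f"{path}/valueFilter", out)
    seen: set[tuple[str, str]] = set()
    for i, af in enumerate(c.attributeFilters):
        _check_term_code(af.attributeCode, f"{path}/attributeFilters/{i}/attributeCode", out)
        if af.attributeCode.key in seen:
            out.append(
                Violation(
                    f"{path}/attributeFilters/{i}",
                    "attribute-codes-distinct",
                    f"duplicate attributeCode {af.attributeCode.system}|{af.attributeCode.code}",
                )
            )
        seen.add(af.attributeCode.key)
        _check_filter(af.filter, f"{path}/attributeFilters/{i}", out)
    tr = c.timeRestriction
    if tr is not None:
        if tr.afterDate is None and tr.beforeDate is None:
            out.append(Violation(f"{path}/timeRestriction", "time-bound-present", "at least one bound must be present"))
        elif tr.afterDate is not None and tr.beforeDate is not None and tr.afterDate > tr.beforeDate:
            out.append(Violation(f"{path}/timeRestriction", "dates-ordered", "afterDate must be <= beforeDate"))


def validate_query(q: CCDLQuery) -> list[Violation]:
    """Re-check every invariant on a query object, returning violations as
    data.  Empty result iff constructing the query from its raw fields would
    raise no error — useful for objects built with ``model_construct``."""
    out: list[Violation] = []
    if not q.version:
        out.append(Violation("/version", "version-non-empty", "version must be non-empty"))
    if not q.inclusionCriteria:
        out.append(Violation("/inclusionCriteria", "inclusion-non-empty", "inclusionCriteria must be non-empty"))
    for i, group in enumerate(q.inclusionCriteria):
        if not group:
            out.append(Violation(f"/inclusionCriteria/{i}", "group-non-empty", "inclusion group is empty"))
        for j, c in enumerate(group):
            _check_criterion(c, f"/inclusionCriteria/{i}/{j}", out)
    if q.exclusionCriteria is not None:
        for i, group in enumerate(q.exclusionCriteria):
            if not group:
                out.append(Violation(f"/exclusionCriteria/{i}", "group-non-empty", "exclusion group is empty"))
            for j, c in enumerate(group):
                _check_criterion(c, f"/exclusionCriteria/{i}/{j}", out)
    return out
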