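"""Document model: parsing, canonical serialization, classification,
validation-as-data."""

import json
from datetime import date
from decimal import Decimal

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccdl.errors import InvariantViolation, MalformedJson, SchemaViolation, UnsupportedVersion
from ccdl.model import (
    SYNTAX_VERSION,
    AttributeFilter,
    CCDLQuery,
    Comparator,
    ConceptFilter,
    Criterion,
    CriterionKind,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    TermCode,
    TimeRestriction,
    Unit,
    classify_criterion,
    parse_query,
    serialize_query,
    validate_query,
)
from conftest import FEMALE, GENDER_CODE, HEMOGLOBIN, ICD10, MALE

E11_QUERY_JSON = json.dumps(
    {
        "version": "1.0",
        "inclusionCriteria": [
            [{"termCodes": [{"system": ICD10, "code": "E11", "display": "Type 2 diabetes mellitus"}]}]
        ],
    }
)


def _exist_criterion(code="E11"):
    return Criterion(termCodes=(TermCode(system=ICD10, code=code),))


def _minimal_query(**kwargs) -> CCDLQuery:
    defaults = dict(version=SYNTAX_VERSION, inclusionCriteria=((_exist_criterion(),),))
    defaults.update(kwargs)
    return CCDLQuery(**defaults)


class TestTermCode:
    def test_identity_is_system_code_pair(self):
        a = TermCode(system=ICD10, code="E11", display="Type 2 diabetes mellitus", version="2024")
        b = TermCode(system=ICD10, code="E11")
        assert a == b and hash(a) == hash(b)
        assert a != TermCode(system=ICD10, code="E10")
        assert a != TermCode(system="http://snomed.info/sct", code="E11")

    @pytest.mark.parametrize("field", ["system", "code"])
    def test_empty_identifier_rejected(self, field):
        kwargs = {"system": ICD10, "code": "E11"}
        kwargs[field] = ""
        with pytest.raises(Exception):
            TermCode(**kwargs)


class TestParse:
    def test_e11_exist_criterion(self):
        q = parse_query(E11_QUERY_JSON)
        assert len(q.inclusionCriteria) == 1 and len(q.inclusionCriteria[0]) == 1
        c = q.inclusionCriteria[0][0]
        assert c.termCodes[0] == TermCode(system=ICD10, code="E11")
        assert classify_criterion(c) is CriterionKind.EXIST
        assert q.exclusionCriteria is None

    def test_not_json(self):
        with pytest.raises(MalformedJson):
            parse_query("{not json")

    def test_empty_inclusion_is_invariant_violation(self):
        with pytest.raises(InvariantViolation):
            parse_query(json.dumps({"version": "1.0", "inclusionCriteria": []}))

    def test_empty_or_group_rejected(self):
        with pytest.raises(InvariantViolation):
            parse_query(json.dumps({"version": "1.0", "inclusionCriteria": [[]]}))

    def test_unknown_member_strict_vs_lenient(self):
        doc = json.loads(E11_QUERY_JSON)
        doc["inclusionCriteria"][0][0]["bogus"] = 1
        text = json.dumps(doc)
        with pytest.raises(SchemaViolation) as exc:
            parse_query(text)
        assert "bogus" in str(exc.value)
        warnings: list[str] = []
        q = parse_query(text, strict=False, warnings=warnings)
        assert q.inclusionCriteria[0][0].termCodes[0].code == "E11"
        assert warnings and "bogus" in warnings[0]

    def test_unsupported_version(self):
        with pytest.raises(UnsupportedVersion):
            parse_query(json.dumps({"version": "99.0", "inclusionCriteria": [[{"termCodes": []}]]}))

    def test_inverted_range_rejected_with_path(self):
        doc = {
            "version": "1.0",
            "inclusionCriteria": [
                [
                    {
                        "termCodes": [{"system": "http://loinc.org", "code": "718-7"}],
                        "valueFilter": {"type": "quantity-range", "minValue": 12, "maxValue": 10},
                    }
                ]
            ],
        }
        with pytest.raises(InvariantViolation) as exc:
            parse_query(json.dumps(doc))
        assert "minValue" in str(exc.value)

    def test_schema_violation_carries_pointer_path(self):
        doc = {"version": "1.0", "inclusionCriteria": [[{"termCodes": [{"system": ICD10}]}]]}
        with pytest.raises(SchemaViolation) as exc:
            parse_query(json.dumps(doc))
        assert exc.value.path.startswith("/inclusionCriteria/0/0/termCodes/0")


class TestSerialize:
    def test_worked_example_members(self):
        q = parse_query(E11_QUERY_JSON)
        out = serialize_query(q)
        assert '"code": "E11"' in out
        assert f'"system": "{ICD10}"' in out
        assert "exclusionCriteria" not in out  # optional member omitted

    def test_canonical_fixpoint(self):
        q = parse_query(E11_QUERY_JSON)
        once = serialize_query(q)
        assert serialize_query(parse_query(once)) == once

    def test_decimal_values_survive_byte_exact(self):
        doc = {
            "version": "1.0",
            "inclusionCriteria": [
                [
                    {
                        "termCodes": [{"system": "http://loinc.org", "code": "718-7"}],
                        "valueFilter": {
                            "type": "quantity-comparator",
                            "comparator": "lt",
                            "value": 12.5,
                            "unit": {"code": "g/dL"},
                        },
                    }
                ]
            ],
        }
        out = serialize_query(parse_query(json.dumps(doc)))
        assert "12.5" in out
        assert serialize_query(parse_query(out)) == out

    def test_invalid_object_rejected(self):
        q = CCDLQuery.model_construct(
            version="1.0", display=None, inclusionCriteria=(), exclusionCriteria=None
        )
        with pytest.raises(InvariantViolation):
            serialize_query(q)


class TestClassify:
    @pytest.mark.parametrize(
        "value_filter,expected",
        [
            (None, CriterionKind.EXIST),
            (
                QuantityComparatorFilter(comparator=Comparator.LT, value=Decimal(12), unit=Unit(code="g/dL")),
                CriterionKind.QUANTITY_COMPARATOR,
            ),
            (
                QuantityRangeFilter(minValue=Decimal(10), maxValue=Decimal(12), unit=Unit(code="g/dL")),
                CriterionKind.QUANTITY_RANGE,
            ),
            (ConceptFilter(selectedConcepts=(FEMALE, MALE)), CriterionKind.VALUE_SET),
        ],
        ids=["exist", "comparator", "range", "value-set"],
    )
    def test_kind_follows_value_filter(self, value_filter, expected):
        code = HEMOGLOBIN if value_filter is not None else GENDER_CODE
        c = Criterion(termCodes=(code,), valueFilter=value_filter)
        assert classify_criterion(c) is expected

    def test_time_restriction_does_not_change_kind(self):
        c = Criterion(
            termCodes=(TermCode(system=ICD10, code="E11"),),
            timeRestriction=TimeRestriction(afterDate=date(2020, 1, 1), beforeDate=date(2021, 1, 1)),
        )
        assert classify_criterion(c) is CriterionKind.EXIST


class TestValidate:
    def test_valid_query_no_violations(self):
        assert validate_query(parse_query(E11_QUERY_JSON)) == []

    def test_inverted_range_reported(self):
        bad_filter = QuantityRangeFilter.model_construct(
            type="quantity-range", minValue=Decimal(12), maxValue=Decimal(10), unit=Unit(code="g/dL")
        )
        c = Criterion.model_construct(
            context=None,
            termCodes=(HEMOGLOBIN,),
            valueFilter=bad_filter,
            attributeFilters=(),
            timeRestriction=None,
        )
        q = _minimal_query(inclusionCriteria=((c,),))
        violations = validate_query(q)
        assert [v.rule for v in violations] == ["range-ordered"]
        assert violations[0].path == "/inclusionCriteria/0/0/valueFilter"

    def test_duplicate_attribute_code_reported(self):
        af = AttributeFilter(
            attributeCode=TermCode(system="http://snomed.info/sct", code="123037004"),
            filter=ConceptFilter(selectedConcepts=(FEMALE,)),
        )
        c = Criterion.model_construct(
            context=None,
            termCodes=(HEMOGLOBIN,),
            valueFilter=None,
            attributeFilters=(af, af),
            timeRestriction=None,
        )
        q = CCDLQuery.model_construct(
            version=SYNTAX_VERSION, display=None, inclusionCriteria=((c,),), exclusionCriteria=None
        )
        assert [v.rule for v in validate_query(q)] == ["attribute-codes-distinct"]

    def test_dates_out_of_order_reported(self):
        tr = TimeRestriction.model_construct(afterDate=date(2021, 1, 1), beforeDate=date(2020, 1, 1))
        c = Criterion.model_construct(
            context=None, termCodes=(HEMOGLOBIN,), valueFilter=None, attributeFilters=(), timeRestriction=tr
        )
        q = _minimal_query(inclusionCriteria=((c,),))
        assert [v.rule for v in validate_query(q)] == ["dates-ordered"]


class TestInvariants:
    def test_time_restriction_requires_a_bound(self):
        with pytest.raises(Exception):
            TimeRestriction()

    def test_attribute_filter_flat_json_round_trip(self):
        doc = {
            "version": "1.0",
            "inclusionCriteria": [
                [
                    {
                        "termCodes": [{"system": "http://snomed.info/sct", "code": "119376003"}],
                        "attributeFilters": [
                            {
                                "attributeCode": {"system": "http://snomed.info/sct", "code": "123037004"},
                                "type": "concept",
                                "selectedConcepts": [{"system": "http://snomed.info/sct", "code": "39937001"}],
                            }
                        ],
                    }
                ]
            ],
        }
        q = parse_query(json.dumps(doc))
        af = q.inclusionCriteria[0][0].attributeFilters[0]
        assert af.attributeCode.code == "123037004"
        assert isinstance(af.filter, ConceptFilter)
        out = serialize_query(q)
        assert parse_query(out) == q

    @settings(deadline=None, derandomize=True)
    @given(
        value=st.decimals(allow_nan=False, allow_infinity=False, places=3, min_value=-10**9, max_value=10**9),
        comparator=st.sampled_from(list(Comparator)),
    )
    def test_quantity_values_round_trip_exactly(self, value, comparator):
        c = Criterion(
            termCodes=(HEMOGLOBIN,),
            valueFilter=QuantityComparatorFilter(comparator=comparator, value=value, unit=Unit(code="g/dL")),
        )
        q = _minimal_query(inclusionCriteria=((c,),))
        text = serialize_query(q)
        q2 = parse_query(text)
        assert q2.inclusionCriteria[0][0].valueFilter.value == value
        assert serialize_query(q2) == text
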