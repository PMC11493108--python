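"""FHIR Search translation: token grammar, parameter conjunction, plans."""

from datetime import date
from decimal import Decimal
from urllib.parse import parse_qsl, urlsplit

import pytest

from ccdl.errors import MappingNotFound, TranslationError, UnmappedReferenceFilter, UnsupportedAttribute
from ccdl.fhir_search import plan_query, predicate_to_search
from ccdl.logic import And, Leaf, Not, expand_criterion, normalize_query
from ccdl.model import (
    SYNTAX_VERSION,
    AttributeFilter,
    CCDLQuery,
    Comparator,
    ConceptFilter,
    Criterion,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    ReferenceFilter,
    TermCode,
    TimeRestriction,
    Unit,
)
from ccdl.synthetic import generate_random_query
from ccdl.terminology import CodeTree, MappingCatalog
from conftest import (
    BODY_SITE,
    C50_0,
    CONDITION_CTX,
    FEMALE,
    HEMOGLOBIN,
    ICD10,
    SKIN,
    TISSUE,
)

EMPTY_TREE = CodeTree(())


def _predicate(criterion: Criterion, tree=EMPTY_TREE):
    return expand_criterion(criterion, tree)


class TestPredicateToSearch:
    def test_condition_worked_example(self, clinical_catalog):
        """The C50.0 condition criterion renders the canonical relative URL."""
        p = _predicate(Criterion(context=CONDITION_CTX, termCodes=(C50_0,)))
        sq = predicate_to_search(p, clinical_catalog)
        assert sq.render() == "Condition?code=http://fhir.de/CodeSystem/bfarm/icd-10-gm|C50.0"

    def test_quantity_comparator_token(self, clinical_catalog):
        p = _predicate(
            Criterion(
                termCodes=(HEMOGLOBIN,),
                valueFilter=QuantityComparatorFilter(
                    comparator=Comparator.LT, value=Decimal(12), unit=Unit(code="g/dL")
                ),
            )
        )
        sq = predicate_to_search(p, clinical_catalog)
        assert ("value-quantity", "lt12|http://unitsofmeasure.org|g/dL") in sq.params

    def test_eq_renders_without_prefix(self, clinical_catalog):
        p = _predicate(
            Criterion(
                termCodes=(HEMOGLOBIN,),
                valueFilter=QuantityComparatorFilter(
                    comparator=Comparator.EQ, value=Decimal("7.5"), unit=Unit(code="g/dL")
                ),
            )
        )
        sq = predicate_to_search(p, clinical_catalog)
        assert ("value-quantity", "7.5|http://unitsofmeasure.org|g/dL") in sq.params

    def test_range_renders_ge_and_le(self, clinical_catalog):
        p = _predicate(
            Criterion(
                termCodes=(HEMOGLOBIN,),
                valueFilter=QuantityRangeFilter(
                    minValue=Decimal(10), maxValue=Decimal(12), unit=Unit(code="g/dL")
                ),
            )
        )
        values = [v for k, v in predicate_to_search(p, clinical_catalog).params if k == "value-quantity"]
        assert values == ["ge10|http://unitsofmeasure.org|g/dL", "le12|http://unitsofmeasure.org|g/dL"]

    def test_specimen_filters_conjoin_on_one_url(self, clinical_catalog):
        """Type, body site and time restriction become distinct parameters
        of one URL — an AND conjunction."""
        p = _predicate(
            Criterion(
                termCodes=(TISSUE,),
                attributeFilters=(
                    AttributeFilter(attributeCode=BODY_SITE, filter=ConceptFilter(selectedConcepts=(SKIN,))),
                ),
                timeRestriction=TimeRestriction(afterDate=date(2020, 1, 1), beforeDate=date(2021, 1, 1)),
            )
        )
        sq = predicate_to_search(p, clinical_catalog)
        assert sq.path == "Specimen"
        names = [k for k, _ in sq.params]
        assert names == ["type", "bodysite", "collected", "collected"]
        assert ("collected", "ge2020-01-01") in sq.params
        assert ("collected", "le2021-01-01") in sq.params

    def test_expanded_codes_comma_join(self, clinical_catalog, e11_tree):
        p = _predicate(Criterion(termCodes=(TermCode(system=ICD10, code="E11"),)), e11_tree)
        sq = predicate_to_search(p, clinical_catalog)
        token = dict(sq.params)["code"]
        assert token.count(",") == 30
        assert token.startswith(f"{ICD10}|E11,")

    def test_unmapped_code_raises(self, clinical_catalog):
        p = _predicate(Criterion(termCodes=(TermCode(system=ICD10, code="Z99"),)))
        with pytest.raises(MappingNotFound):
            predicate_to_search(p, clinical_catalog)

    def test_unknown_attribute_raises(self, clinical_catalog):
        p = _predicate(
            Criterion(
                termCodes=(TISSUE,),
                attributeFilters=(
                    AttributeFilter(
                        attributeCode=TermCode(system="http://snomed.info/sct", code="0000"),
                        filter=ConceptFilter(selectedConcepts=(SKIN,)),
                    ),
                ),
            )
        )
        with pytest.raises(UnsupportedAttribute):
            predicate_to_search(p, clinical_catalog)

    def test_reference_filter_without_target_raises(self, clinical_catalog):
        p = _predicate(
            Criterion(
                termCodes=(TISSUE,),
                attributeFilters=(
                    AttributeFilter(attributeCode=BODY_SITE, filter=ReferenceFilter(selectedConcepts=(SKIN,))),
                ),
            )
        )
        with pytest.raises(UnmappedReferenceFilter):
            predicate_to_search(p, clinical_catalog)


class TestPlanQuery:
    def _portal_style_query(self) -> CCDLQuery:
        # four inclusion criteria (leukocytes in range, brain neoplasm,
        # tissue specimen, imaging after a date) and one excluded medication
        def cond(code):
            return Criterion(termCodes=(TermCode(system=ICD10, code=code),))

        inclusion = ((cond("C71"),), (cond("D33"),), (cond("R94"),), (cond("Z01"),))
        exclusion = ((cond("Y43.3"),),)
        return CCDLQuery(version=SYNTAX_VERSION, inclusionCriteria=inclusion, exclusionCriteria=exclusion)

    @pytest.fixture()
    def condition_catalog(self, clinical_catalog):
        from ccdl.terminology import MappingEntry

        entries = list(clinical_catalog.entries)
        for code in ("C71", "D33", "R94", "Z01", "Y43.3"):
            entries.append(
                MappingEntry(termCode=TermCode(system=ICD10, code=code), resourceType="Condition")
            )
        return MappingCatalog(entries)

    def test_inclusion_and_not_exclusion_shape(self, condition_catalog):
        plan = plan_query(normalize_query(self._portal_style_query(), EMPTY_TREE), condition_catalog)
        assert len(plan.leaves) == 5
        root = plan.combiner
        assert isinstance(root, And) and len(root.children) == 2
        inclusion, negation = root.children
        assert isinstance(inclusion, And) and len(inclusion.children) == 4
        assert isinstance(negation, Not) and isinstance(negation.child, Leaf)

    def test_single_criterion_plan(self, clinical_catalog):
        q = CCDLQuery(
            version=SYNTAX_VERSION,
            inclusionCriteria=((Criterion(context=CONDITION_CTX, termCodes=(C50_0,)),),),
        )
        plan = plan_query(normalize_query(q, EMPTY_TREE), clinical_catalog)
        assert list(plan.rendered().values()) == [
            "Condition?code=http://fhir.de/CodeSystem/bfarm/icd-10-gm|C50.0"
        ]
        assert isinstance(plan.combiner, Leaf)

    def test_rendering_deterministic(self, forest, catalog):
        q = generate_random_query(5, forest, catalog)
        plan_a = plan_query(normalize_query(q, forest), catalog)
        plan_b = plan_query(normalize_query(q, forest), catalog)
        assert plan_a.to_data() == plan_b.to_data()

    def test_translation_errors_aggregate(self, clinical_catalog):
        q = CCDLQuery(
            version=SYNTAX_VERSION,
            inclusionCriteria=(
                (Criterion(termCodes=(TermCode(system=ICD10, code="Z98"),)),),
                (Criterion(termCodes=(TermCode(system=ICD10, code="Z99"),)),),
            ),
        )
        with pytest.raises(TranslationError) as exc:
            plan_query(normalize_query(q, EMPTY_TREE), clinical_catalog)
        assert len(exc.value.failures) == 2

    def test_urls_parse_and_distinct_predicates_render_distinct(self, forest, catalog):
        seen: dict[str, str] = {}
        for seed in range(60):
            q = generate_random_query(seed, forest, catalog)
            plan = plan_query(normalize_query(q, forest), catalog)
            urls = plan.rendered()
            for leaf, leaf_id in plan.leaf_ids.items():
                url = urls[leaf_id]
                split = urlsplit("https://example.org/fhir/" + url)
                assert split.path.endswith("/" + plan.leaves[leaf_id].path)
                assert parse_qsl(split.query, separator="&")
                # Injectivity holds modulo context: the context is carried
                # into the URL only through the mapping entry it selects, so
                # predicates identical except for an advisory context that
                # resolves to the same entry render identically.
                key = repr(
                    (leaf.predicate.codeSet, leaf.predicate.valueFilter,
                     leaf.predicate.attributeFilters, leaf.predicate.timeRestriction)
                )
                if url in seen:
                    assert seen[url] == key
                seen[url] = key


class TestCommaJoinSemantics:
    def test_token_or_equals_union_of_single_code_queries(self, e11_tree, clinical_catalog):
        """The comma-joined token parameter's OR semantics coincide with the
        union of per-code evaluations (FHIR OR == expansion OR)."""
        from ccdl.evaluator import evaluate_criterion_set
        from ccdl.synthetic import generate_random_dataset
        from ccdl.terminology import MappingEntry

        entries = list(clinical_catalog.entries) + [
            MappingEntry(termCode=TermCode(system=ICD10, code="E11"), context=CONDITION_CTX, resourceType="Condition")
        ]
        # a dataset whose condition events use E11 subtree codes
        from random import Random

        from ccdl.evaluator import ClinicalEvent, PatientRecord

        rng = Random(3)
        codes = [t for t in e11_tree.codes()]
        dataset = [
            PatientRecord(
                patientId=f"p{i}",
                events=[
                    ClinicalEvent(context=CONDITION_CTX, code=rng.choice(codes))
                    for _ in range(rng.randint(0, 3))
                ],
            )
            for i in range(80)
        ]
        parent = expand_criterion(Criterion(termCodes=(TermCode(system=ICD10, code="E11"),)), e11_tree)
        combined = evaluate_criterion_set(parent, dataset)
        union: set[str] = set()
        for code in parent.codeSet:
            single = expand_criterion(Criterion(termCodes=(code,)), CodeTree(()))
            union |= evaluate_criterion_set(single, dataset)
        assert combined == union
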