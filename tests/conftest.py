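import pytest

from ccdl.model import ContextCode, TermCode
from ccdl.synthetic import CodeTreeSpec, build_mapping_catalog, e11_code_tree, generate_code_tree
from ccdl.terminology import AttributeMapping, MappingCatalog, MappingEntry

ICD10 = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
LOINC = "http://loinc.org"
SNOMED = "http://snomed.info/sct"
GENDER = "http://hl7.org/fhir/administrative-gender"

HEMOGLOBIN = TermCode(system=LOINC, code="718-7", display="Hemoglobin")
GENDER_CODE = TermCode(system=LOINC, code="46098-0", display="Sex")
TISSUE = TermCode(system=SNOMED, code="119376003", display="Tissue specimen")
C50_0 = TermCode(system=ICD10, code="C50.0", display="Malignant neoplasm: nipple and areola")
MI = TermCode(system=ICD10, code="I21", display="Acute myocardial infarction")
BODY_SITE = TermCode(system=SNOMED, code="123037004", display="Body site")
SKIN = TermCode(system=SNOMED, code="39937001", display="Skin")
MUCOSA = TermCode(system=SNOMED, code="113277000", display="Mucosa")
FEMALE = TermCode(system=GENDER, code="female")
MALE = TermCode(system=GENDER, code="male")

CONDITION_CTX = ContextCode(system="http://example.org/fhir/CodeSystem/context", code="Condition")
CAUSE_OF_DEATH_CTX = ContextCode(system="http://example.org/fhir/CodeSystem/context", code="CauseOfDeath")


@pytest.fixture(scope="session")
def e11_tree():
    return e11_code_tree()


@pytest.fixture(scope="session")
def forest():
    """Default synthetic forest: 4 systems x 2 roots, depth 2, branching 3."""
    return generate_code_tree(CodeTreeSpec(), seed=1)


@pytest.fixture(scope="session")
def catalog(forest):
    return build_mapping_catalog(forest)


def _condition_entry(code: TermCode, context=None) -> MappingEntry:
    return MappingEntry(
        termCode=code,
        context=context,
        resourceType="Condition",
        termCodeSearchParam="code",
        timeParam="recorded-date",
        cqlRetrieveTemplate="Condition.code",
        cqlTimePath="recordedDate",
    )


@pytest.fixture(scope="session")
def clinical_catalog():
    """Hand-built catalog with realistic clinical entries: hemoglobin,
    gender, tissue specimens, a breast-cancer condition code, and a
    myocardial-infarction code mapped in two contexts."""
    entries = [
        MappingEntry(
            termCode=HEMOGLOBIN,
            resourceType="Observation",
            termCodeSearchParam="code",
            valueSearchParam="value-quantity",
            valueTypeHint="quantity",
            timeParam="date",
            cqlRetrieveTemplate="Observation.code",
            cqlValuePath="value",
            cqlTimePath="effective",
        ),
        MappingEntry(
            termCode=GENDER_CODE,
            resourceType="Observation",
            termCodeSearchParam="code",
            valueSearchParam="value-concept",
            valueTypeHint="concept",
            timeParam="date",
            cqlRetrieveTemplate="Observation.code",
            cqlValuePath="value",
            cqlTimePath="effective",
        ),
        MappingEntry(
            termCode=TISSUE,
            resourceType="Specimen",
            termCodeSearchParam="type",
            attributeParams={BODY_SITE.key: AttributeMapping("bodysite", "concept", "collection.bodySite")},
            timeParam="collected",
            cqlRetrieveTemplate="Specimen.type",
            cqlTimePath="collection.collected",
        ),
        _condition_entry(C50_0),
        _condition_entry(TermCode(system=ICD10, code="E11")),
        _condition_entry(MI, context=CONDITION_CTX),
        MappingEntry(
            termCode=MI,
            context=CAUSE_OF_DEATH_CTX,
            resourceType="Observation",
            termCodeSearchParam="code",
            timeParam="date",
            cqlRetrieveTemplate="Observation.code",
            cqlTimePath="effective",
        ),
    ]
    return MappingCatalog(entries)
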