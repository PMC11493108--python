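"""Synthetic terminology, query and patient-data generators.

Everything the stack needs for testing is generated here with no external
downloads: ICD-10-like code hierarchies (plus the verbatim type-2-diabetes
E11 subtree), a mapping catalog wired to four data-model profiles
(conditions, quantity and concept observations, specimens), random valid
and mappable feasibility queries, and patient datasets — either with
planted cohort structure and an explicit ground-truth table, or fully
random for oracle comparisons.

All generators are deterministic under their seed.  Generated code
surfaces are ICD-10-like for readability only; no semantic claims attach
to them.
"""

from __future__ import annotations

import csv
import io
import json
from datetime import date, timedelta
from decimal import Decimal
from pathlib import Path
from random import Random
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigInvalid
from .evaluator import ClinicalEvent, Dataset, PatientRecord, Quantity, dump_dataset
from .logic import expand_criterion
from .model import (
    SYNTAX_VERSION,
    AttributeFilter,
    CCDLQuery,
    Comparator,
    ConceptFilter,
    ContextCode,
    Criterion,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    TermCode,
    TimeRestriction,
    Unit,
    serialize_query,
)
from .terminology import (
    AttributeMapping,
    CodeTree,
    CodeTreeNode,
    MappingCatalog,
    MappingEntry,
    dump_code_tree,
    dump_mapping_catalog,
)

# Code systems used by the synthetic world.
ICD10_SYSTEM = "http://fhir.de/CodeSystem/bfarm/icd-10-gm"
CONTEXT_SYSTEM = "http://example.org/fhir/CodeSystem/context"
VALUE_SYSTEM = "http://example.org/fhir/CodeSystem/values"
ATTRIBUTE_SYSTEM = "http://example.org/fhir/CodeSystem/attributes"
DISTRACTOR_SYSTEM = "http://example.org/fhir/CodeSystem/distractor"


def synthetic_system(index: int) -> str:
    return f"http://example.org/fhir/CodeSystem/synthetic-{index}"


#: Concept-value pool shared by query and dataset generators (small on
#: purpose, so value-set criteria actually hit events).
VALUE_POOL = tuple(TermCode(system=VALUE_SYSTEM, code=f"v{i}") for i in range(6))

BODY_SITE_ATTR = TermCode(system=ATTRIBUTE_SYSTEM, code="body-site", display="Body site")
STATUS_ATTR = TermCode(system=ATTRIBUTE_SYSTEM, code="status", display="Status")

#: UCUM codes the generators draw from.
UNIT_POOL = (Unit(code="g/dL"), Unit(code="mmol/L"))


# ---------------------------------------------------------------------------
# E11 fixture: the type 2 diabetes mellitus subtree
# ---------------------------------------------------------------------------

# Pre-order layout of ICD-10-GM E11 and its 30 subtypes.
_E11_LAYOUT: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("E11.3", ("E11.31", "E11.30")),
    ("E11.1", ("E11.11",)),
    ("E11.0", ("E11.01",)),
    ("E11.7", ("E11.75", "E11.74", "E11.73", "E11.72")),
    ("E11.4", ("E11.41", "E11.40")),
    ("E11.8", ("E11.81", "E11.80")),
    ("E11.2", ("E11.21", "E11.20")),
    ("E11.5", ("E11.51", "E11.50")),
    ("E11.6", ("E11.61", "E11.60")),
    ("E11.9", ("E11.91", "E11.90")),
)


def e11_code_tree() -> CodeTree:
    """The ICD-10-GM subtree for type 2 diabetes mellitus (E11): the parent
    code plus its 30 subtypes, used to exercise hierarchy expansion."""

    def code(c: str) -> TermCode:
        return TermCode(system=ICD10_SYSTEM, code=c)

    children = tuple(
        CodeTreeNode(code(sub), tuple(CodeTreeNode(code(leaf)) for leaf in leaves))
        for sub, leaves in _E11_LAYOUT
    )
    root = CodeTreeNode(TermCode(system=ICD10_SYSTEM, code="E11", display="Type 2 diabetes mellitus"), children)
    return CodeTree((root,))


def e11_codes() -> set[str]:
    """The expected membership of the E11 expansion (31 codes)."""
    out = {"E11"}
    for sub, leaves in _E11_LAYOUT:
        out.add(sub)
        out.update(leaves)
    return out


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


class CodeTreeSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    depth: int = 2  # levels below each root
    branching: int = 3
    nSystems: int = 4
    rootsPerSystem: int = 2

    def _check(self) -> None:
        if self.depth < 1 or self.branching < 1 or self.nSystems < 1 or self.rootsPerSystem < 1:
            raise ConfigInvalid("codeTreeSpec values must all be >= 1")


class NormalDist(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["normal"] = "normal"
    mean: float
    sd: float
    unit: Optional[str] = None


class CategoricalDist(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["categorical"] = "categorical"
    weights: dict[str, float]  # concept code (in the value pool system) -> weight


ValueDistribution = Union[NormalDist, CategoricalDist]


class PlantSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)
    criterion: Criterion
    targetPrevalence: float

    def _check(self) -> None:
        if not 0.0 <= self.targetPrevalence <= 1.0:
            raise ConfigInvalid("targetPrevalence must lie in [0, 1]")


class DateRange(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: date = date(2019, 1, 1)
    end: date = date(2022, 12, 31)

    def _check(self) -> None:
        if self.start > self.end:
            raise ConfigInvalid("dateRange start must be <= end")


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic world; deterministic under seed."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    nPatients: int = 100
    nQueries: int = 10
    codeTreeSpec: CodeTreeSpec = Field(default_factory=CodeTreeSpec)
    plantSpec: list[PlantSpec] = Field(default_factory=list)
    dateRange: DateRange = Field(default_factory=DateRange)
    valueDistributions: dict[str, ValueDistribution] = Field(default_factory=dict)

    def check(self) -> "GeneratorConfig":
        if self.nPatients < 1:
            raise ConfigInvalid("nPatients must be positive")
        self.codeTreeSpec._check()
        for p in self.plantSpec:
            p._check()
        self.dateRange._check()
        return self


def load_generator_config(json_text: str) -> GeneratorConfig:
    try:
        data = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ConfigInvalid(f"config is not valid JSON: {exc}") from exc
    try:
        return GeneratorConfig.model_validate(data).check()
    except ValidationError as exc:
        raise ConfigInvalid(str(exc.errors()[0]["msg"])) from exc


# ---------------------------------------------------------------------------
# Code trees
# ---------------------------------------------------------------------------

_LETTERS = "ABCDFGHJKLMNPRSTUVWY"


def generate_code_tree(spec: CodeTreeSpec, seed: int) -> CodeTree:
    """A forest of full trees with ICD-10-like codes ("X99.9" shapes),
    ``rootsPerSystem`` roots in each of ``nSystems`` code systems."""
    spec._check()
    rng = Random(seed)
    roots: list[CodeTreeNode] = []
    for s in range(spec.nSystems):
        system = synthetic_system(s)
        for r in range(spec.rootsPerSystem):
            letter = _LETTERS[(s * spec.rootsPerSystem + r) % len(_LETTERS)]
            stem = f"{letter}{rng.randint(10, 99)}"

            def build(code: str, level: int) -> CodeTreeNode:
                if level >= spec.depth:
                    return CodeTreeNode(TermCode(system=system, code=code))
                sep = "." if "." not in code else ""
                children = tuple(build(f"{code}{sep}{i}", level + 1) for i in range(spec.branching))
                return CodeTreeNode(TermCode(system=system, code=code), children)

            roots.append(build(stem, 0))
    return CodeTree(tuple(roots))


# ---------------------------------------------------------------------------
# Mapping catalog
# ---------------------------------------------------------------------------

_PROFILES = ("Condition", "Observation-quantity", "Observation-concept", "Specimen")


def _entry_for(term_code: TermCode, profile: str, context: Optional[ContextCode] = None) -> MappingEntry:
    common_attrs = {
        BODY_SITE_ATTR.key: AttributeMapping("body-site", "concept", "bodySite"),
        STATUS_ATTR.key: AttributeMapping("status", "concept", "status"),
    }
    if profile == "Condition":
        return MappingEntry(
            termCode=term_code,
            context=context,
            resourceType="Condition",
            termCodeSearchParam="code",
            attributeParams=common_attrs,
            timeParam="recorded-date",
            cqlRetrieveTemplate="Condition.code",
            cqlTimePath="recordedDate",
        )
    if profile == "Observation-quantity":
        return MappingEntry(
            termCode=term_code,
            context=context,
            resourceType="Observation",
            termCodeSearchParam="code",
            valueSearchParam="value-quantity",
            valueTypeHint="quantity",
            attributeParams=common_attrs,
            timeParam="date",
            cqlRetrieveTemplate="Observation.code",
            cqlValuePath="value",
            cqlTimePath="effective",
        )
    if profile == "Observation-concept":
        return MappingEntry(
            termCode=term_code,
            context=context,
            resourceType="Observation",
            termCodeSearchParam="code",
            valueSearchParam="value-concept",
            valueTypeHint="concept",
            attributeParams=common_attrs,
            timeParam="date",
            cqlRetrieveTemplate="Observation.code",
            cqlValuePath="value",
            cqlTimePath="effective",
        )
    return MappingEntry(
        termCode=term_code,
        context=context,
        resourceType="Specimen",
        termCodeSearchParam="type",
        attributeParams={BODY_SITE_ATTR.key: AttributeMapping("bodysite", "concept", "collection.bodySite")},
        timeParam="collected",
        cqlRetrieveTemplate="Specimen.type",
        cqlTimePath="collection.collected",
    )


def profile_context(entry: MappingEntry) -> ContextCode:
    """The context code the synthetic world pairs with a mapping entry."""
    return ContextCode(system=CONTEXT_SYSTEM, code=entry.resourceType)


def build_mapping_catalog(tree: CodeTree) -> MappingCatalog:
    """One context-free entry per code in the forest, cycling systems
    through the four data-model profiles in sorted-system order."""
    systems = sorted({root.termCode.system for root in tree.roots})
    profile_of = {system: _PROFILES[i % len(_PROFILES)] for i, system in enumerate(systems)}
    entries = [
        _entry_for(code, profile_of[code.system])
        for code in sorted(tree.codes(), key=lambda t: t.key)
    ]
    return MappingCatalog(entries)


# ---------------------------------------------------------------------------
# Random queries
# ---------------------------------------------------------------------------


def _random_date(rng: Random, lo: date, hi: date) -> date:
    return lo + timedelta(days=rng.randint(0, (hi - lo).days))


def _random_decimal(rng: Random) -> Decimal:
    return Decimal(rng.randint(0, 1000)) / 10


def _random_time_restriction(rng: Random, lo: date, hi: date) -> TimeRestriction:
    shape = rng.random()
    a, b = sorted((_random_date(rng, lo, hi), _random_date(rng, lo, hi)))
    if shape < 0.6:
        return TimeRestriction(afterDate=a, beforeDate=b)
    if shape < 0.8:
        return TimeRestriction(afterDate=a)
    return TimeRestriction(beforeDate=b)


def _random_criterion(rng: Random, entries: list[MappingEntry], lo: date, hi: date) -> Criterion:
    entry = rng.choice(entries)
    term_codes = [entry.termCode]
    if rng.random() < 0.15:
        peers = [e for e in entries if e.resourceType == entry.resourceType and e.termCode != entry.termCode]
        if peers:
            term_codes.append(rng.choice(peers).termCode)

    value_filter = None
    if entry.valueTypeHint == "quantity":
        roll = rng.random()
        if roll < 0.4:
            unit = rng.choice(UNIT_POOL)
            value_filter = QuantityComparatorFilter(
                comparator=rng.choice(list(Comparator)), value=_random_decimal(rng), unit=unit
            )
        elif roll < 0.7:
            a, b = sorted((_random_decimal(rng), _random_decimal(rng)))
            value_filter = QuantityRangeFilter(minValue=a, maxValue=b, unit=rng.choice(UNIT_POOL))
    elif entry.valueTypeHint == "concept" and rng.random() < 0.6:
        k = rng.randint(1, 3)
        value_filter = ConceptFilter(selectedConcepts=tuple(rng.sample(VALUE_POOL, k)))

    attribute_filters: list[AttributeFilter] = []
    if entry.attributeParams and rng.random() < 0.3:
        attr_key = rng.choice(sorted(entry.attributeParams))
        concepts = tuple(rng.sample(VALUE_POOL, rng.randint(1, 2)))
        attribute_filters.append(
            AttributeFilter(
                attributeCode=TermCode(system=attr_key[0], code=attr_key[1]),
                filter=ConceptFilter(selectedConcepts=concepts),
            )
        )

    return Criterion(
        context=profile_context(entry) if rng.random() < 0.5 else None,
        termCodes=tuple(term_codes),
        valueFilter=value_filter,
        attributeFilters=tuple(attribute_filters),
        timeRestriction=_random_time_restriction(rng, lo, hi) if rng.random() < 0.3 else None,
    )


def generate_random_query(seed: int, tree: CodeTree, catalog: MappingCatalog) -> CCDLQuery:
    """A schema-valid, fully mappable random query exercising all four
    criterion kinds, multi-termCode criteria, attribute filters, time
    restrictions and 0-3 exclusion groups."""
    rng = Random(seed)
    entries = [e for e in catalog.entries if e.context is None]
    lo, hi = date(2019, 1, 1), date(2022, 12, 31)
    inclusion = tuple(
        tuple(_random_criterion(rng, entries, lo, hi) for _ in range(rng.randint(1, 3)))
        for _ in range(rng.randint(1, 3))
    )
    n_exclusion = rng.choices((0, 1, 2, 3), weights=(0.45, 0.3, 0.15, 0.1))[0]
    exclusion = (
        tuple(
            tuple(_random_criterion(rng, entries, lo, hi) for _ in range(rng.randint(1, 2)))
            for _ in range(n_exclusion)
        )
        or None
    )
    return CCDLQuery(
        version=SYNTAX_VERSION,
        display=f"synthetic query {seed}",
        inclusionCriteria=inclusion,
        exclusionCriteria=exclusion,
    )


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


def _matching_event(rng: Random, criterion: Criterion, tree: CodeTree, catalog: MappingCatalog) -> ClinicalEvent:
    """Construct one event that satisfies every part of a criterion."""
    from .terminology import lookup_mapping

    predicate = expand_criterion(criterion, tree)
    code = rng.choice(predicate.codeSet)
    entry = lookup_mapping(None, criterion.termCodes[0], catalog)
    context = criterion.context if criterion.context is not None else profile_context(entry)

    value = None
    vf = criterion.valueFilter
    if isinstance(vf, ConceptFilter):
        value = rng.choice(vf.selectedConcepts)
    elif isinstance(vf, QuantityComparatorFilter):
        delta = Decimal(rng.randint(1, 50)) / 10
        base = vf.value
        observed = {
            "eq": base,
            "ne": base + delta,
            "lt": base - delta,
            "le": base,
            "gt": base + delta,
            "ge": base,
        }[vf.comparator.value]
        value = Quantity(value=observed, unit=vf.unit)
    elif isinstance(vf, QuantityRangeFilter):
        value = Quantity(value=(vf.minValue + vf.maxValue) / 2, unit=vf.unit)

    attributes = {}
    for af in criterion.attributeFilters:
        f = af.filter
        if isinstance(f, ConceptFilter):
            attributes[af.attributeCode.key] = rng.choice(f.selectedConcepts)
        elif isinstance(f, QuantityComparatorFilter):
            attributes[af.attributeCode.key] = Quantity(value=f.value, unit=f.unit)
        elif isinstance(f, QuantityRangeFilter):
            attributes[af.attributeCode.key] = Quantity(value=(f.minValue + f.maxValue) / 2, unit=f.unit)
        else:  # reference: degenerate concept semantics
            attributes[af.attributeCode.key] = rng.choice(f.selectedConcepts)

    tr = criterion.timeRestriction
    if tr is not None:
        a = tr.afterDate if tr.afterDate is not None else (tr.beforeDate - timedelta(days=365))
        b = tr.beforeDate if tr.beforeDate is not None else (tr.afterDate + timedelta(days=365))
        event_date = _random_date(rng, a, b)
    else:
        event_date = _random_date(rng, date(2019, 1, 1), date(2022, 12, 31)) if rng.random() < 0.8 else None

    return ClinicalEvent(context=context, code=code, value=value, attributes=attributes, date=event_date)


def _distractor_event(rng: Random, lo: date, hi: date) -> ClinicalEvent:
    return ClinicalEvent(
        context=ContextCode(system=CONTEXT_SYSTEM, code="Condition"),
        code=TermCode(system=DISTRACTOR_SYSTEM, code=f"d{rng.randint(0, 19)}"),
        date=_random_date(rng, lo, hi) if rng.random() < 0.8 else None,
    )


def _distribution_event(rng: Random, key: str, dist: ValueDistribution, lo: date, hi: date) -> ClinicalEvent:
    system, _, code = key.partition("|")
    if isinstance(dist, NormalDist):
        observed = Decimal(f"{rng.gauss(dist.mean, dist.sd):.1f}")
        value: object = Quantity(value=observed, unit=Unit(code=dist.unit) if dist.unit else None)
        context = ContextCode(system=CONTEXT_SYSTEM, code="Observation")
    else:
        codes = sorted(dist.weights)
        chosen = rng.choices(codes, weights=[dist.weights[c] for c in codes])[0]
        value = TermCode(system=VALUE_SYSTEM, code=chosen)
        context = ContextCode(system=CONTEXT_SYSTEM, code="Observation")
    return ClinicalEvent(
        context=context,
        code=TermCode(system=system, code=code),
        value=value,
        date=_random_date(rng, lo, hi) if rng.random() < 0.8 else None,
    )


def generate_dataset(
    config: GeneratorConfig, tree: CodeTree, catalog: MappingCatalog
) -> tuple[Dataset, dict[int, frozenset[str]]]:
    """Patients with planted cohort structure.

    For each plant-spec entry, exactly ``round(targetPrevalence *
    nPatients)`` patients (seeded sample) receive one event matching the
    criterion; the returned ground truth maps the plant index to exactly
    those patient ids.  Distractor events use a code system no query ever
    references, so a planted criterion's evaluated set equals its ground
    truth as long as plant criteria do not overlap in codes.
    """
    config.check()
    rng = Random(config.seed)
    ids = [f"p{i:04d}" for i in range(config.nPatients)]
    patients = {pid: PatientRecord(patientId=pid) for pid in ids}
    lo, hi = config.dateRange.start, config.dateRange.end

    ground_truth: dict[int, frozenset[str]] = {}
    for index, plant in enumerate(config.plantSpec):
        k = round(plant.targetPrevalence * config.nPatients)
        chosen = rng.sample(ids, k)
        ground_truth[index] = frozenset(chosen)
        for pid in chosen:
            patients[pid].events.append(_matching_event(rng, plant.criterion, tree, catalog))

    for pid in ids:
        for _ in range(rng.randint(2, 8)):
            patients[pid].events.append(_distractor_event(rng, lo, hi))
        for key, dist in sorted(config.valueDistributions.items()):
            if rng.random() < 0.5:
                patients[pid].events.append(_distribution_event(rng, key, dist, lo, hi))

    return [patients[pid] for pid in ids], ground_truth


def generate_random_dataset(seed: int, tree: CodeTree, catalog: MappingCatalog, n_patients: int = 500) -> Dataset:
    """Unplanted random patients whose events are drawn from the catalog's
    own codes, values and attributes — the substrate for oracle-equivalence
    testing where no ground truth is assumed."""
    rng = Random(seed)
    entries = [e for e in catalog.entries if e.context is None]
    lo, hi = date(2019, 1, 1), date(2022, 12, 31)
    patients: Dataset = []
    for i in range(n_patients):
        events = []
        for _ in range(rng.randint(3, 10)):
            entry = rng.choice(entries)
            node = tree.node(entry.termCode)
            if node is not None and node.children and rng.random() < 0.5:
                code = rng.choice([c.termCode for c in node.children])
            else:
                code = entry.termCode
            value = None
            if entry.valueTypeHint == "quantity":
                value = Quantity(value=_random_decimal(rng), unit=rng.choice(UNIT_POOL))
            elif entry.valueTypeHint == "concept":
                value = rng.choice(VALUE_POOL)
            attributes = {}
            for attr_key in sorted(entry.attributeParams):
                if rng.random() < 0.4:
                    attributes[attr_key] = rng.choice(VALUE_POOL)
            events.append(
                ClinicalEvent(
                    context=profile_context(entry),
                    code=code,
                    value=value,
                    attributes=attributes,
                    date=_random_date(rng, lo, hi) if rng.random() < 0.85 else None,
                )
            )
        patients.append(PatientRecord(patientId=f"p{i:04d}", events=events))
    return patients


# ---------------------------------------------------------------------------
# Fixture-set writer
# ---------------------------------------------------------------------------


def ground_truth_csv(ground_truth: dict[int, frozenset[str]]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["plant_index", "patient_id"])
    for index in sorted(ground_truth):
        for pid in sorted(ground_truth[index]):
            writer.writerow([index, pid])
    return buf.getvalue()


def write_fixture_set(config: GeneratorConfig, out_dir: Path) -> dict:
    """Write the full fixture set (tree, catalog, dataset, ground truth,
    queries, manifest) into a directory; idempotent for a given config."""
    config.check()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = generate_code_tree(config.codeTreeSpec, config.seed)
    catalog = build_mapping_catalog(tree)
    dataset, ground_truth = generate_dataset(config, tree, catalog)

    (out_dir / "code_tree.json").write_text(dump_code_tree(tree))
    (out_dir / "mapping_catalog.json").write_text(dump_mapping_catalog(catalog))
    (out_dir / "dataset.jsonl").write_text(dump_dataset(dataset))
    (out_dir / "ground_truth.csv").write_text(ground_truth_csv(ground_truth))

    queries_dir = out_dir / "queries"
    queries_dir.mkdir(exist_ok=True)
    query_files = []
    for i in range(config.nQueries):
        q = generate_random_query(config.seed * 10_000 + i, tree, catalog)
        name = f"query_{i:03d}.json"
        (queries_dir / name).write_text(serialize_query(q))
        query_files.append(name)

    manifest = {
        "seed": config.seed,
        "nPatients": config.nPatients,
        "nQueries": config.nQueries,
        "plantSpecs": len(config.plantSpec),
        "files": {
            "codeTree": "code_tree.json",
            "mappingCatalog": "mapping_catalog.json",
            "dataset": "dataset.jsonl",
            "groundTruth": "ground_truth.csv",
            "queries": [f"queries/{n}" for n in query_files],
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
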