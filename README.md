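# ccdl — Clinical Cohort Definition Language toolkit

Before a clinical study starts, researchers ask a *feasibility question*:
how many patients in a data repository satisfy a set of eligibility
criteria?  Answering this across heterogeneous repositories is hard
because every system speaks its own query language (FHIR Search, CQL,
AQL, SQL, ...).  The Clinical Cohort Definition Language (CCDL) is an
intermediate, data-model-agnostic JSON syntax for such feasibility
queries: a user interface emits one CCDL document, and each repository
translates it into its native language.

This package implements the language end to end for research-informatics
developers and integrators:

- a **validated document model** for CCDL JSON (parse, canonical
  serialize, classify, validate),
- the **boolean semantics**: inclusion criteria in conjunctive normal
  form, exclusion criteria in disjunctive normal form, combined as
  `inclusion AND NOT exclusion`, with the implicit expansion layer
  (OR across a criterion's term codes and across a parent code's
  terminology descendants; OR across selected value-set concepts; AND
  across a criterion's filters),
- **translators** to FHIR Search (one site-relative URL per criterion
  plus a combiner tree) and to CQL (one self-contained library per
  query, checked by a grammar-subset linter),
- a **reference evaluator** that computes feasibility counts over
  synthetic patient data — the ground-truth semantics both translators
  must honor,
- **seeded generators** for code hierarchies, mapping catalogs, random
  queries and patient datasets with planted cohort structure.

## The language in a nutshell

A query is a JSON document

```
inclusionCriteria : [[c11, c12], [c21], ...]   — CNF: AND of OR groups
exclusionCriteria : [[d11, d12], [d21], ...]   — DNF: OR of AND groups
```

and its cohort is

```
( ⋂ groups  ⋃ members )  \  ( ⋃ groups  ⋂ members )
```

— no negation exists anywhere inside either structure.  The atomic
criterion is a clinical concept identified by `(system, code)` term
codes (e.g. ICD-10-GM `E11`), optionally disambiguated by a *context*
(myocardial infarction as diagnosis vs cause of death), and restricted
by at most one value filter (quantity comparison such as
hemoglobin < 12 g/dL, inclusive quantity range, or a value-set
selection), attribute filters (e.g. body site = skin for a tissue
specimen) and an inclusive calendar-date window.  Every filter on one
criterion must hold on the *same* clinical event.

A criterion whose code is a parent in the terminology hierarchy expands
implicitly to the OR of its whole subtree: selecting `E11` searches all
31 codes of the type-2-diabetes subtree.

Translation needs the knowledge the agnostic syntax deliberately drops:
a *mapping catalog* reattaches, per `(context, termCode)`, the target
endpoint (`/Condition`), its search parameters (`code`,
`value-quantity`, ...) and CQL retrieve paths.

## Worked example

```python
from ccdl import *
from ccdl.synthetic import (GeneratorConfig, PlantSpec, build_mapping_catalog,
                            e11_code_tree, generate_dataset)

tree = e11_code_tree()                       # ICD-10-GM E11 subtree, 31 codes
catalog = build_mapping_catalog(tree)
e11 = Criterion(termCodes=(TermCode(system="http://fhir.de/CodeSystem/bfarm/icd-10-gm",
                                    code="E11", display="Type 2 diabetes mellitus"),))
query = CCDLQuery(version="1.0", inclusionCriteria=((e11,),))

config = GeneratorConfig(seed=42, nPatients=200,
                         plantSpec=[PlantSpec(criterion=e11, targetPrevalence=0.15)])
dataset, truth = generate_dataset(config, tree, catalog)

print(f"expanded codes: {len(expand_code(e11.termCodes[0], tree))}")
result = run_query(query, dataset, tree)
print(f"cohort size:    {result.count} of {len(dataset)} patients")
print(f"ground truth:   {len(truth[0])} planted patients, "
      f"match={set(result.patientIds) == truth[0]}")
```

prints

```
expanded codes: 31
cohort size:    30 of 200 patients
ground truth:   30 planted patients, match=True
```

The parent code `E11` matched patients planted with any of its subtypes
(hierarchy expansion), and the evaluated cohort is exactly the planted
15 % of 200 patients.  The same query translates to a single FHIR
Search URL whose `code` parameter comma-joins all 31 `system|code`
tokens (FHIR's native OR), and to a CQL library:

```
library CCDL_772e2ac47b22 version '1.0.0'

using FHIR version '4.0.1'

codesystem cs_1: 'http://fhir.de/CodeSystem/bfarm/icd-10-gm'

context Patient

define Criterion_1:
  exists ([Condition: code in { Code 'E11' from cs_1, Code 'E11.3' from cs_1, ... }])
```

## Command line

```sh
ccdl validate query.json                       # exit 0 iff no violations
ccdl translate query.json --target fhir-search --tree tree.json --catalog catalog.json
ccdl translate query.json --target cql         --tree tree.json --catalog catalog.json
ccdl run query.json dataset.jsonl --tree tree.json     # prints the cohort size
ccdl gen config.json --out-dir fixtures/       # full synthetic fixture set
```

Exit codes: 0 success, 1 validation failure, 2 translation failure,
3 I/O or configuration failure.

## Scope

The package covers the feasibility-query syntax and its translation;
it does not implement federation infrastructure, live terminology
servers, HTTP execution against FHIR endpoints, CQL/ELM compilation,
AQL emission, or temporal relations *between* criteria (the language
itself has none).
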