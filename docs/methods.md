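# Methods

This note records the semantics this package fixes, the design choices
made where the language description leaves room, what the synthetic
generators do and do not emulate, and the problem sizes the automated
checks use.

## Language semantics

**Boolean layer.** A query's cohort is defined set-algebraically:
inclusion criteria form a CNF (outer list AND, inner lists OR),
exclusion criteria a DNF (outer list OR, inner lists AND), and the
result is the inclusion set minus the exclusion set.  Consequences we
fix as contract:

- A patient satisfying both inclusion and exclusion is excluded
  (asymmetric difference, not symmetric).
- Exclusion criteria are evaluated against the whole dataset, not only
  against inclusion survivors — mathematically identical under set
  difference, stated to pin down the execution contract.
- An absent `exclusionCriteria` member simply means no subtraction.
- Negation never occurs inside the CNF/DNF structures; in the
  normalized plan `NOT` appears exactly once, as the root's second
  operand, and nowhere below.

**Normalization.** `normalize_query` builds an expression tree whose
leaves are criteria after implicit expansion.  Singleton groups collapse
to their only member (an OR of one is that one).  Children at every
level are ordered lexicographically by their first code-set element so
that a given query and code tree always produce the identical plan and
therefore byte-identical translation artifacts.

**Implicit expansion.** A criterion's code set is the union of the
hierarchy expansions of its term codes: alternatives across
terminologies are OR choices, and a parent code means OR over its whole
subtree (pre-order, duplicate-free, the query's own code first).  The
expansion is realized as a code *set* attached to one predicate rather
than one OR node per descendant — semantically identical to the OR
chain while keeping plans small.  Expansion applies to
criterion-identifying codes only; the concepts inside a value-set
filter are matched verbatim.  Value-set selections are OR across the
selected concepts; all filters on one criterion are AND, and all must
hold on the *same* clinical event (a tissue specimen with body site
skin is one object's properties, never two events' properties combined).

**Matching details** (fixed where the language is silent):

- Date windows and quantity ranges are inclusive on both ends.
- Units compare by exact UCUM code string; there is no unit conversion.
  A mismatch is a non-match: differing units signal a data problem, not
  an equivalence.
- `ne` matches only when a numeric value is present and differs; an
  absent value never matches any value filter (no negation-as-failure
  on missing data).
- The comparator vocabulary is {eq, ne, lt, le, gt, ge}.
- A criterion's optional context must equal the event's context when
  present; an absent context matches any event.
- Dates are calendar dates (ISO `YYYY-MM-DD`), no time of day.
- The query subject is the patient; encounter- or specimen-level
  counting is out of scope.

**Reference filters.** The attribute-filter variant `reference` is
structurally modeled and preserved.  Its execution semantics are not
fully specified by the language, so the evaluator gives it the minimal
executable meaning — the event's attribute holds a term code among the
selected concepts (degenerating to concept semantics) — and the
translators emit it only when the mapping declares a reference target,
erroring otherwise.

**Versioning.** The syntax version is an opaque string compared for
equality; this implementation accepts exactly `"1.0"` and raises
`UnsupportedVersion` for anything else, so future dialects fail loudly
rather than silently misparse.

## Parsing and canonical serialization

Schema validation is enforced through typed pydantic models (strict
mode rejects unknown members with a JSON-pointer path; lenient mode
drops them and records warnings).  A JSON Schema document describing
the accepted dialect ships in `src/ccdl/schemas/` as the external
interface description.  Numeric literals are read as exact decimals and
re-emitted in plain notation (no exponent, no trailing fractional
zeros); member order is fixed per object type and optional members are
omitted.  Together this makes `serialize ∘ parse ∘ serialize` a
byte-level fixpoint, which the round-trip corpus checks.

Term-code identity is the `(system, code)` pair; `display` and
`version` are annotations that never affect equality, hashing, or
set-membership anywhere in the stack.

## Terminology knowledge

Code hierarchies are forests of trees, not DAGs: a code appears at most
once, children share their parent's system, and multi-parent codes must
be duplicated at authoring time.  Mapping lookup precedence is a total
order: exact `(context, termCode)` entry, then the context-free entry
for the code, then — only when explicitly enabled and a tree is
supplied — the nearest mapped ancestor, then `MappingNotFound`.
Ancestor fallback is off by default because query author and executor
are expected to agree on terminology entries exactly.

## Translation

**FHIR Search.** Each predicate becomes one site-relative URL (the base
URL is never embedded).  OR across codes is one comma-joined token
parameter (`system|code,...`), FHIR's native OR; AND across filters is
one parameter per filter on the same URL, FHIR's native AND.  Quantity
tokens carry the comparator prefix (`lt12|http://unitsofmeasure.org|g/dL`);
equality renders with no prefix (FHIR's default).  Ranges become a
`ge`/`le` parameter pair, date windows `ge`/`le` on the mapped date
parameter.  Parameter order is canonical: term-code token, value,
attributes (sorted by parameter name), time.  Because FHIR Search has
no global negation, the exclusion `NOT` stays in the plan's combiner
tree for client-side set algebra.  Note that a context is carried into
the URL only through the mapping entry it selects; two predicates
identical except for an advisory context that resolves to the same
entry render the same search.

**CQL.** One library per query: a `define Criterion_<i>` per predicate
(`exists` over a retrieve filtered by the expanded code list, filters
ANDed in a `where` clause) and a `define InInitialPopulation` with the
query's boolean skeleton.  Code membership is rendered as an explicit
inline code list rather than external value-set references, keeping
libraries self-contained and mirroring expansion-at-translation.  The
library name derives from a hash of the canonical query serialization
(reproducible, cache-keyable).  Output validity is defined by the
grammar-subset linter in `ccdl.cql` — header shape, declared-before-use
code-system aliases, unique defines, balanced parentheses/quotes, and a
parseable boolean skeleton — not by a full CQL engine; surface syntax
beyond that subset is this package's own choice and is verified
structurally (skeleton isomorphic to the normalized plan), never by
execution.

## Synthetic data: what it emulates, what it does not

The generators produce ICD-10-like code forests (default: 4 systems ×
2 roots, depth 2, branching 3 — 104 codes), a mapping catalog cycling
the systems through four data-model profiles (condition, quantity
observation, concept observation, specimen), random queries drawn from
that catalog (1–3 inclusion groups of 1–3 criteria; exclusion group
count 0–3 with weights 0.45/0.3/0.15/0.1; value/attribute/time filter
rates 0.6/0.3/0.3; contexts on half the criteria), and patient event
stores.  Quantity values are uniform on [0, 100] with one decimal digit
on both the query and data sides, concept values come from a shared
six-concept pool, and event dates span 2019–2022; these shared
conventions exist so that generated queries hit generated data at
informative, non-degenerate rates.  All generators are deterministic
under their seed.

Planted datasets construct, for each plant specification, one event
that satisfies every part of the target criterion for exactly
`round(prevalence × nPatients)` seeded-sampled patients, and emit that
membership as an explicit ground-truth table (emitted, not re-derived,
so evaluator tests are oracle-grade).  Distractor events use a
dedicated code system no query ever references; a planted criterion's
evaluated set therefore equals its ground truth exactly, provided plant
criteria do not overlap in codes.

What the synthetic world does **not** emulate: real epidemiological
prevalence and co-occurrence structure, realistic terminology sizes,
unit heterogeneity requiring conversion, missing-data patterns of real
EHRs, or free-text/postcoordinated codes.  Passing tests demonstrate
that the semantics, translators and evaluator agree with the language
definition — not that real-world repositories would return clinically
meaningful counts.

## Verification strategy and problem sizes

The engine is never its own witness.  An independent brute-force
evaluator (`tests/_bruteforce.py`) re-implements the raw per-patient
CNF/DNF/AND-NOT definition — including its own subtree walk and event
matching — and the main acceptance property compares the two on 200
seeded query/dataset pairs of 500 patients each (exact set equality).
Canonical round-tripping runs over a 500-query corpus; the implicit-
logic laws (value-set OR as union; filters never enlarging; exclusion
never enlarging) are each checked over ≥100 seeds on 100-patient
datasets; CQL structural fidelity over 200 queries.  These sizes keep
the full suite under half a minute on one CPU while exercising every
criterion kind and filter variant (the generators' coverage is itself
asserted).

## Known limitations

- No temporal relations between criteria and no cardinality operators —
  the language has none, deliberately.
- Trees only (no DAG terminologies); no live terminology-server
  expansion.
- FHIR Search plans require client-side set algebra for the exclusion
  branch; no `_has`/chained parameters, paging, or HTTP execution.
- CQL output is validated structurally by the bundled linter, not
  compiled to ELM or executed.
- Unit equality is literal UCUM-code equality; convertible units
  (mg/dL vs mmol/L) do not match by design.
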