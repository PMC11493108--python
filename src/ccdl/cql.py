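"""CQL emission: one library text per query.

Each atomic predicate becomes a ``define Criterion_<i>`` with an
``exists`` over a retrieve filtered by the expanded code list; the entry
point ``InInitialPopulation`` combines the defines with the query's
boolean skeleton.  Code membership is rendered as an explicit inline code
list (self-contained libraries, mirroring expansion at translation time).

Output validity is defined by the grammar-subset linter in this module:
header shape, declared-before-use code system aliases, unique define
names, balanced parentheses and quotes, and a parseable boolean skeleton
for the entry define.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Optional

from .errors import CCDLError, TranslationError, UnmappedReferenceFilter, UnsupportedAttribute
from .logic import And, ExpressionTree, Leaf, Node, Not, Or, iter_leaves, normalize_query
from .model import (
    CCDLQuery,
    ConceptFilter,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    ReferenceFilter,
    _decimal_str,
    serialize_query,
)
from .terminology import CodeTree, MappingCatalog, MappingEntry, lookup_mapping

FHIR_VERSION = "4.0.1"

_CQL_OP = {"eq": "=", "ne": "!=", "lt": "<", "le": "<=", "gt": ">", "ge": ">="}


@dataclass
class CqlLibrary:
    """A rendered CQL library: header declarations plus ordered defines."""

    libraryName: str
    fhirVersionDecl: str
    codesystems: dict[str, str]  # alias -> system URI
    defines: list[tuple[str, str]]  # (name, expression text)
    entry_define: str = "InInitialPopulation"

    def to_text(self) -> str:
        lines = [f"library {self.libraryName} version '1.0.0'", ""]
        lines.append(f"using FHIR version '{self.fhirVersionDecl}'")
        lines.append("")
        for alias, uri in self.codesystems.items():
            lines.append(f"codesystem {alias}: '{uri}'")
        if self.codesystems:
            lines.append("")
        lines.append("context Patient")
        lines.append("")
        for name, expr in self.defines:
            lines.append(f"define {name}:")
            lines.append(f"  {expr}")
            lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _collect_systems(t: ExpressionTree) -> list[str]:
    systems: list[str] = []
    seen: set[str] = set()

    def add(uri: str) -> None:
        if uri not in seen:
            seen.add(uri)
            systems.append(uri)

    for leaf in iter_leaves(t):
        p = leaf.predicate
        for code in p.codeSet:
            add(code.system)
        if isinstance(p.valueFilter, ConceptFilter):
            for c in p.valueFilter.selectedConcepts:
                add(c.system)
        for af in p.attributeFilters:
            if isinstance(af.filter, (ConceptFilter, ReferenceFilter)):
                for c in af.filter.selectedConcepts:
                    add(c.system)
    return sorted(systems)


def _code_literal(t, aliases: dict[str, str]) -> str:
    return f"Code '{t.code}' from {aliases[t.system]}"


def _code_list(codes, aliases: dict[str, str]) -> str:
    return "{ " + ", ".join(_code_literal(c, aliases) for c in codes) + " }"


def _quantity_literal(value, unit) -> str:
    if unit is None:
        return _decimal_str(value)
    return f"{_decimal_str(value)} '{unit.code}'"


def _filter_clause(path: str, f, aliases: dict[str, str]) -> str:
    if isinstance(f, (ConceptFilter, ReferenceFilter)):
        return f"E.{path} in {_code_list(f.selectedConcepts, aliases)}"
    if isinstance(f, QuantityComparatorFilter):
        return f"E.{path} {_CQL_OP[f.comparator.value]} {_quantity_literal(f.value, f.unit)}"
    if isinstance(f, QuantityRangeFilter):
        return (
            f"E.{path} >= {_quantity_literal(f.minValue, f.unit)} "
            f"and E.{path} <= {_quantity_literal(f.maxValue, f.unit)}"
        )
    raise UnsupportedAttribute(f"cannot render filter {type(f).__name__}")


def predicate_to_define(
    p,
    catalog: MappingCatalog,
    index: int,
    aliases: dict[str, str],
    tree: Optional[CodeTree] = None,
) -> tuple[str, str]:
    """Render one predicate as ``(name, expression)``: an ``exists`` over a
    retrieve filtered by the expanded code list, with all filters ANDed in
    a where clause."""
    entry: MappingEntry = lookup_mapping(p.context, p.codeSet[0], catalog, tree)
    resource, _, code_path = entry.cqlRetrieveTemplate.partition(".")
    retrieve = f"[{resource}: {code_path or 'code'} in {_code_list(p.codeSet, aliases)}]"

    clauses: list[str] = []
    if p.valueFilter is not None:
        if entry.cqlValuePath is None:
            raise UnsupportedAttribute(
                f"mapping for {entry.termCode.system}|{entry.termCode.code} defines no CQL value path"
            )
        clauses.append(_filter_clause(entry.cqlValuePath, p.valueFilter, aliases))
    for af in p.attributeFilters:
        am = entry.attributeParams.get(af.attributeCode.key)
        if am is None or am.cqlPath is None:
            raise UnsupportedAttribute(
                f"attribute {af.attributeCode.system}|{af.attributeCode.code} has no CQL path "
                f"in the mapping for {entry.termCode.system}|{entry.termCode.code}"
            )
        if isinstance(af.filter, ReferenceFilter) and am.typeHint != "reference":
            raise UnmappedReferenceFilter(
                f"attribute {af.attributeCode.system}|{af.attributeCode.code} carries a reference "
                "filter but the mapping declares no reference target"
            )
        clauses.append(_filter_clause(am.cqlPath, af.filter, aliases))
    if p.timeRestriction is not None:
        if entry.cqlTimePath is None:
            raise UnsupportedAttribute(
                f"mapping for {entry.termCode.system}|{entry.termCode.code} defines no CQL time path"
            )
        tr, tp = p.timeRestriction, entry.cqlTimePath
        if tr.afterDate is not None and tr.beforeDate is not None:
            clauses.append(f"E.{tp} in Interval[@{tr.afterDate.isoformat()}, @{tr.beforeDate.isoformat()}]")
        elif tr.afterDate is not None:
            clauses.append(f"E.{tp} >= @{tr.afterDate.isoformat()}")
        else:
            clauses.append(f"E.{tp} <= @{tr.beforeDate.isoformat()}")

    if clauses:
        expr = f"exists ({retrieve} E where {' and '.join(clauses)})"
    else:
        expr = f"exists ({retrieve})"
    return (f"Criterion_{index}", expr)


def _render_skeleton(n: Node, names: dict[Leaf, str]) -> str:
    def wrap(child: Node) -> str:
        rendered = _render_skeleton(child, names)
        if isinstance(child, (And, Or)):
            return f"({rendered})"
        return rendered

    if isinstance(n, Leaf):
        return names[n]
    if isinstance(n, Not):
        return f"not ({_render_skeleton(n.child, names)})"
    joiner = " and " if isinstance(n, And) else " or "
    return joiner.join(wrap(c) for c in n.children)


def build_library(
    t: ExpressionTree,
    q: CCDLQuery,
    catalog: MappingCatalog,
    tree: Optional[CodeTree] = None,
) -> CqlLibrary:
    systems = _collect_systems(t)
    aliases = {uri: f"cs_{i + 1}" for i, uri in enumerate(systems)}
    names: dict[Leaf, str] = {}
    defines: list[tuple[str, str]] = []
    failures: list[tuple[str, Exception]] = []
    for leaf in iter_leaves(t):
        if leaf in names:
            continue
        index = len(names) + 1
        names[leaf] = f"Criterion_{index}"
        try:
            defines.append(predicate_to_define(leaf.predicate, catalog, index, aliases, tree))
        except Exception as exc:  # noqa: BLE001 - aggregated and re-raised
            failures.append((f"Criterion_{index}", exc))
    if failures:
        raise TranslationError(failures)
    defines.append(("InInitialPopulation", _render_skeleton(t, names)))
    digest = hashlib.sha256(serialize_query(q).encode()).hexdigest()[:12]
    return CqlLibrary(
        libraryName=f"CCDL_{digest}",
        fhirVersionDecl=FHIR_VERSION,
        codesystems={aliases[uri]: uri for uri in systems},
        defines=defines,
    )


def query_to_cql(q: CCDLQuery, tree: CodeTree, catalog: MappingCatalog) -> str:
    """Render the full library text for a query; deterministic byte-for-byte."""
    plan = normalize_query(q, tree)
    return build_library(plan, q, catalog, tree).to_text()


# ---------------------------------------------------------------------------
# Grammar-subset linter
# ---------------------------------------------------------------------------


class CqlLintError(CCDLError):
    """The library text violates the accepted CQL grammar subset."""


_LIBRARY_RE = re.compile(r"^library (\w+) version '[^']*'$")
_USING_RE = re.compile(r"^using FHIR version '([^']*)'$")
_CODESYSTEM_RE = re.compile(r"^codesystem (\w+): '([^']+)'$")
_DEFINE_RE = re.compile(r"^define (\w+):$")
_FROM_RE = re.compile(r"\bfrom (\w+)\b")
_SKELETON_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z_]\w*)")


@dataclass
class LintedLibrary:
    libraryName: str
    codesystems: dict[str, str]
    defines: dict[str, str]
    skeleton: object  # boolean skeleton of the entry define


def _strip_strings(text: str) -> str:
    return re.sub(r"'[^']*'", "''", text)


def _parse_skeleton(expr: str):
    """Parse ``and``/``or``/``not``/parenthesis structure over identifiers.

    ``or`` binds loosest, then ``and``, then ``not``; chains collect into
    n-ary nodes so the result mirrors the expression-tree arity.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _SKELETON_TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise CqlLintError(f"unexpected token in boolean skeleton near {expr[pos:pos + 20]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    i = 0

    def peek():
        return tokens[i] if i < len(tokens) else None

    def eat(tok: str) -> None:
        nonlocal i
        if peek() != tok:
            raise CqlLintError(f"expected {tok!r}, found {peek()!r}")
        i += 1

    def parse_or():
        parts = [parse_and()]
        while peek() == "or":
            eat("or")
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else ("or", tuple(parts))

    def parse_and():
        parts = [parse_unary()]
        while peek() == "and":
            eat("and")
            parts.append(parse_unary())
        return parts[0] if len(parts) == 1 else ("and", tuple(parts))

    def parse_unary():
        nonlocal i
        tok = peek()
        if tok == "not":
            eat("not")
            return ("not", parse_unary())
        if tok == "(":
            eat("(")
            inner = parse_or()
            eat(")")
            return inner
        if tok is None or tok in (")", "and", "or"):
            raise CqlLintError(f"unexpected token {tok!r} in boolean skeleton")
        i += 1
        return ("ref", tok)

    result = parse_or()
    if i != len(tokens):
        raise CqlLintError(f"trailing tokens in boolean skeleton: {tokens[i:]}")
    return result


def lint_library(text: str) -> LintedLibrary:
    """Check a library against the grammar subset and return its structure."""
    lines = text.split("\n")
    idx = 0

    def next_nonblank() -> str:
        nonlocal idx
        while idx < len(lines) and not lines[idx].strip():
            idx += 1
        if idx >= len(lines):
            raise CqlLintError("unexpected end of library text")
        line = lines[idx]
        idx += 1
        return line

    m = _LIBRARY_RE.match(next_nonblank())
    if m is None:
        raise CqlLintError("missing or malformed library declaration")
    library_name = m.group(1)
    if _USING_RE.match(next_nonblank()) is None:
        raise CqlLintError("missing or malformed using declaration")

    codesystems: dict[str, str] = {}
    line = next_nonblank()
    while (m := _CODESYSTEM_RE.match(line)) is not None:
        alias, uri = m.group(1), m.group(2)
        if alias in codesystems:
            raise CqlLintError(f"codesystem alias {alias!r} declared twice")
        codesystems[alias] = uri
        line = next_nonblank()
    if line.strip() != "context Patient":
        raise CqlLintError("missing context declaration")

    defines: dict[str, str] = {}
    order: list[str] = []
    name = None
    body: list[str] = []
    while idx <= len(lines):
        raw = lines[idx] if idx < len(lines) else None
        idx += 1
        header = _DEFINE_RE.match(raw.strip()) if raw is not None else None
        if header is not None or raw is None:
            if name is not None:
                expr = " ".join(part.strip() for part in body if part.strip())
                if name in defines:
                    raise CqlLintError(f"define {name!r} declared twice")
                defines[name] = expr
                order.append(name)
            if raw is None:
                break
            name, body = header.group(1), []
        elif name is not None:
            body.append(raw)
        elif raw.strip():
            raise CqlLintError(f"unexpected line outside defines: {raw.strip()!r}")

    if not defines:
        raise CqlLintError("library declares no defines")
    for define_name, expr in defines.items():
        stripped = _strip_strings(expr)
        if stripped.count("'") % 2:
            raise CqlLintError(f"unbalanced quotes in define {define_name!r}")
        depth = 0
        for ch in stripped:
            if ch == "(" or ch == "[":
                depth += 1
            elif ch == ")" or ch == "]":
                depth -= 1
                if depth < 0:
                    raise CqlLintError(f"unbalanced parentheses in define {define_name!r}")
        if depth != 0:
            raise CqlLintError(f"unbalanced parentheses in define {define_name!r}")
        for alias in _FROM_RE.findall(stripped):
            if alias not in codesystems:
                raise CqlLintError(f"define {define_name!r} references undeclared codesystem alias {alias!r}")

    if "InInitialPopulation" not in defines:
        raise CqlLintError("missing entry define InInitialPopulation")
    skeleton = _parse_skeleton(defines["InInitialPopulation"])

    def check_refs(node) -> None:
        kind = node[0]
        if kind == "ref":
            if node[1] not in defines:
                raise CqlLintError(f"InInitialPopulation references undefined name {node[1]!r}")
        elif kind == "not":
            check_refs(node[1])
        else:
            for child in node[1]:
                check_refs(child)

    check_refs(skeleton)
    return LintedLibrary(
        libraryName=library_name,
        codesystems=codesystems,
        defines=defines,
        skeleton=skeleton,
    )


def skeleton_of_tree(t: Node, names: dict[Leaf, str]):
    """Boolean skeleton of an expression tree in the linter's representation,
    for isomorphism checks against a re-parsed library."""
    if isinstance(t, Leaf):
        return ("ref", names[t])
    if isinstance(t, Not):
        return ("not", skeleton_of_tree(t.child, names))
    tag = "and" if isinstance(t, And) else "or"
    return (tag, tuple(skeleton_of_tree(c, names) for c in t.children))
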