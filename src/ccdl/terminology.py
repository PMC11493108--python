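"""Terminology knowledge reattached at translation and execution time.

Two artifacts live here.  A :class:`CodeTree` is a forest of code-system
hierarchies used for the implicit OR expansion of parent codes into their
descendants.  A :class:`MappingCatalog` carries the data-model-specific
knowledge (endpoint, search parameters, CQL paths) that reconnects the
data-model-agnostic criteria of a query to a concrete repository.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import DuplicateKey, MalformedJson, MappingNotFound, SchemaViolation
from .model import ContextCode, TermCode

Key = tuple[str, str]


# ---------------------------------------------------------------------------
# Code trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodeTreeNode:
    termCode: TermCode
    children: tuple["CodeTreeNode", ...] = ()


class CodeTree:
    """A forest of terminology hierarchies indexed by (system, code).

    Trees, not DAGs: a (system, code) pair may appear at most once in the
    forest, and every child shares its parent's code system.
    """

    def __init__(self, roots: tuple[CodeTreeNode, ...] = ()) -> None:
        self.roots = tuple(roots)
        self._index: dict[Key, CodeTreeNode] = {}
        self._parent: dict[Key, Key] = {}
        for root in self.roots:
            self._register(root, None)

    def _register(self, node: CodeTreeNode, parent: Optional[CodeTreeNode]) -> None:
        key = node.termCode.key
        if key in self._index:
            raise DuplicateKey(f"code {key[0]}|{key[1]} appears twice in the forest")
        if parent is not None and node.termCode.system != parent.termCode.system:
            raise SchemaViolation(
                f"child {node.termCode.code} has system {node.termCode.system!r} "
                f"but parent {parent.termCode.code} has {parent.termCode.system!r}"
            )
        self._index[key] = node
        if parent is not None:
            self._parent[key] = parent.termCode.key
        for child in node.children:
            self._register(child, node)

    def __contains__(self, t: TermCode) -> bool:
        return t.key in self._index

    def __len__(self) -> int:
        return len(self._index)

    def node(self, t: TermCode) -> Optional[CodeTreeNode]:
        return self._index.get(t.key)

    def parent(self, t: TermCode) -> Optional[TermCode]:
        key = self._parent.get(t.key)
        return self._index[key].termCode if key is not None else None

    def codes(self) -> Iterator[TermCode]:
        return (n.termCode for n in self._index.values())


def expand_code(t: TermCode, tree: CodeTree) -> list[TermCode]:
    """Expand a criterion-identifying code into itself plus all descendants.

    Selecting a parent code means OR over its whole subtree; the result is
    the input followed by every descendant in deterministic pre-order.  A
    code absent from the forest expands to itself alone.
    """
    node = tree.node(t)
    if node is None:
        return [t]
    out: list[TermCode] = []

    def visit(n: CodeTreeNode) -> None:
        out.append(n.termCode)
        for child in n.children:
            visit(child)

    visit(node)
    return out


# ---------------------------------------------------------------------------
# Mapping catalog
# ---------------------------------------------------------------------------

TypeHint = Literal["concept", "quantity", "reference"]


@dataclass(frozen=True)
class AttributeMapping:
    searchParam: str
    typeHint: TypeHint
    cqlPath: Optional[str] = None


@dataclass(frozen=True)
class MappingEntry:
    """How one (context, termCode) criterion reaches a concrete data model:
    the target endpoint, its search parameters, and CQL retrieve paths."""

    termCode: TermCode
    context: Optional[ContextCode] = None
    resourceType: str = ""
    termCodeSearchParam: str = "code"
    valueSearchParam: Optional[str] = None
    valueTypeHint: Optional[TypeHint] = None
    attributeParams: dict[Key, AttributeMapping] = field(default_factory=dict)
    timeParam: Optional[str] = None
    cqlRetrieveTemplate: str = ""
    cqlValuePath: Optional[str] = None
    cqlTimePath: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.resourceType:
            raise SchemaViolation("mapping entry resourceType must be non-empty")
        if not self.termCodeSearchParam:
            raise SchemaViolation("mapping entry termCodeSearchParam must be non-empty")
        if not self.cqlRetrieveTemplate:
            object.__setattr__(self, "cqlRetrieveTemplate", f"{self.resourceType}.code")


class MappingCatalog:
    """Lookup structure over mapping entries.

    At most one entry per (context, termCode) pair and at most one
    context-free entry per termCode.
    """

    def __init__(self, entries: list[MappingEntry]) -> None:
        self.entries = list(entries)
        self._exact: dict[tuple[Key, Key], MappingEntry] = {}
        self._free: dict[Key, MappingEntry] = {}
        for e in self.entries:
            if e.context is not None:
                k = (e.context.key, e.termCode.key)
                if k in self._exact:
                    raise DuplicateKey(
                        f"two entries for context {e.context.system}|{e.context.code}, "
                        f"termCode {e.termCode.system}|{e.termCode.code}"
                    )
                self._exact[k] = e
            else:
                if e.termCode.key in self._free:
                    raise DuplicateKey(
                        f"two context-free entries for termCode {e.termCode.system}|{e.termCode.code}"
                    )
                self._free[e.termCode.key] = e

    def __len__(self) -> int:
        return len(self.entries)


def lookup_mapping(
    context: Optional[ContextCode],
    t: TermCode,
    catalog: MappingCatalog,
    tree: Optional[CodeTree] = None,
    ancestor_fallback: bool = False,
) -> MappingEntry:
    """Resolve the mapping entry for a criterion key.

    Precedence: exact (context, termCode) match, then the context-free entry
    for the termCode.  With ``ancestor_fallback`` enabled (off by default)
    and a code tree supplied, unresolved codes retry on their nearest mapped
    ancestor.  Failure raises :class:`MappingNotFound`, signalling that the
    query author and the executor disagree on terminology entries.
    """
    probe: Optional[TermCode] = t
    while probe is not None:
        if context is not None:
            entry = catalog._exact.get((context.key, probe.key))
            if entry is not None:
                return entry
        entry = catalog._free.get(probe.key)
        if entry is not None:
            return entry
        if not (ancestor_fallback and tree is not None):
            break
        probe = tree.parent(probe)
    raise MappingNotFound(context, t)


# ---------------------------------------------------------------------------
# JSON loaders / writers
# ---------------------------------------------------------------------------


class _NodeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    system: str
    code: str
    display: Optional[str] = None
    children: list["_NodeModel"] = []


class _ForestModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    roots: list[_NodeModel] = []


class _TermCodeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    system: str
    code: str
    version: Optional[str] = None
    display: Optional[str] = None


class _AttributeParamModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    searchParam: str
    typeHint: TypeHint
    cqlPath: Optional[str] = None


class _EntryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    termCode: _TermCodeModel
    context: Optional[_TermCodeModel] = None
    resourceType: str
    termCodeSearchParam: str = "code"
    valueSearchParam: Optional[str] = None
    valueTypeHint: Optional[TypeHint] = None
    attributeParams: dict[str, _AttributeParamModel] = {}
    timeParam: Optional[str] = None
    cqlRetrieveTemplate: str = ""
    cqlValuePath: Optional[str] = None
    cqlTimePath: Optional[str] = None


class _CatalogModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    entries: list[_EntryModel] = []


def _attr_key(raw: str) -> Key:
    system, sep, code = raw.partition("|")
    if not sep or not system or not code:
        raise SchemaViolation(f"attributeParams key {raw!r} must look like 'system|code'")
    return (system, code)


def _build_node(m: _NodeModel) -> CodeTreeNode:
    return CodeTreeNode(
        termCode=TermCode(system=m.system, code=m.code, display=m.display),
        children=tuple(_build_node(c) for c in m.children),
    )


def load_code_tree(json_text: str) -> CodeTree:
    """Load a code-tree forest from its JSON interchange form
    (``{"roots": [{system, code, display?, children: [...]}, ...]}``)."""
    try:
        data = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise MalformedJson(str(exc)) from exc
    try:
        forest = _ForestModel.model_validate(data)
    except ValidationError as exc:
        raise SchemaViolation(str(exc.errors()[0]["msg"])) from exc
    return CodeTree(tuple(_build_node(r) for r in forest.roots))


def load_mapping_catalog(json_text: str) -> MappingCatalog:
    """Load a mapping catalog from its flat JSON entry list
    (``{"entries": [...]}``)."""
    try:
        data = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise MalformedJson(str(exc)) from exc
    try:
        cm = _CatalogModel.model_validate(data)
    except ValidationError as exc:
        raise SchemaViolation(str(exc.errors()[0]["msg"])) from exc
    entries = []
    for em in cm.entries:
        entries.append(
            MappingEntry(
                termCode=TermCode(**em.termCode.model_dump()),
                context=ContextCode(**em.context.model_dump()) if em.context is not None else None,
                resourceType=em.resourceType,
                termCodeSearchParam=em.termCodeSearchParam,
                valueSearchParam=em.valueSearchParam,
                valueTypeHint=em.valueTypeHint,
                attributeParams={
                    _attr_key(k): AttributeMapping(v.searchParam, v.typeHint, v.cqlPath)
                    for k, v in em.attributeParams.items()
                },
                timeParam=em.timeParam,
                cqlRetrieveTemplate=em.cqlRetrieveTemplate,
                cqlValuePath=em.cqlValuePath,
                cqlTimePath=em.cqlTimePath,
            )
        )
    return MappingCatalog(entries)


def _node_data(n: CodeTreeNode) -> dict:
    out: dict = {"system": n.termCode.system, "code": n.termCode.code}
    if n.termCode.display is not None:
        out["display"] = n.termCode.display
    if n.children:
        out["children"] = [_node_data(c) for c in n.children]
    return out


def dump_code_tree(tree: CodeTree) -> str:
    return json.dumps({"roots": [_node_data(r) for r in tree.roots]}, indent=2) + "\n"


def _entry_data(e: MappingEntry) -> dict:
    out: dict = {"termCode": {"system": e.termCode.system, "code": e.termCode.code}}
    if e.termCode.display is not None:
        out["termCode"]["display"] = e.termCode.display
    if e.context is not None:
        out["context"] = {"system": e.context.system, "code": e.context.code}
        if e.context.display is not None:
            out["context"]["display"] = e.context.display
    out["resourceType"] = e.resourceType
    out["termCodeSearchParam"] = e.termCodeSearchParam
    if e.valueSearchParam is not None:
        out["valueSearchParam"] = e.valueSearchParam
    if e.valueTypeHint is not None:
        out["valueTypeHint"] = e.valueTypeHint
    if e.attributeParams:
        out["attributeParams"] = {
            f"{k[0]}|{k[1]}": {
                "searchParam": v.searchParam,
                "typeHint": v.typeHint,
                **({"cqlPath": v.cqlPath} if v.cqlPath is not None else {}),
            }
            for k, v in sorted(e.attributeParams.items())
        }
    if e.timeParam is not None:
        out["timeParam"] = e.timeParam
    out["cqlRetrieveTemplate"] = e.cqlRetrieveTemplate
    if e.cqlValuePath is not None:
        out["cqlValuePath"] = e.cqlValuePath
    if e.cqlTimePath is not None:
        out["cqlTimePath"] = e.cqlTimePath
    return out


def dump_mapping_catalog(catalog: MappingCatalog) -> str:
    return json.dumps({"entries": [_entry_data(e) for e in catalog.entries]}, indent=2) + "\n"
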