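"""Exception hierarchy shared by all CCDL components."""

from __future__ import annotations


class CCDLError(Exception):
    """Base class for every error raised by this package."""


class MalformedJson(CCDLError):
    """Input text is not parseable JSON."""


class SchemaViolation(CCDLError):
    """JSON is structurally wrong: missing, ill-typed or unknown member.

    ``path`` is a JSON-pointer-style location of the offending member.
    """

    def __init__(self, message: str, path: str = "") -> None:
        super().__init__(f"{path or '/'}: {message}" if path else message)
        self.path = path
        self.reason = message


class InvariantViolation(CCDLError):
    """Structurally valid JSON that breaks a semantic invariant
    (empty criterion group, inverted quantity range, ...)."""

    def __init__(self, message: str, path: str = "") -> None:
        super().__init__(f"{path or '/'}: {message}" if path else message)
        self.path = path
        self.reason = message


class UnsupportedVersion(CCDLError):
    """Query declares a syntax version this implementation does not accept."""


class DuplicateKey(CCDLError):
    """A terminology artifact defines the same lookup key twice."""


class MappingNotFound(CCDLError):
    """No mapping-catalog entry resolves the (context, termCode) key.

    Signals disagreement between the query author's ontology and the
    executor's catalog.
    """

    def __init__(self, context, term_code) -> None:
        ctx = f"context={context.system}|{context.code}, " if context is not None else ""
        super().__init__(f"no mapping entry for {ctx}termCode={term_code.system}|{term_code.code}")
        self.context = context
        self.term_code = term_code


class UnsupportedAttribute(CCDLError):
    """The mapping entry does not define how to translate a filter the
    predicate uses (an attribute code, a value filter, a time restriction)."""


class UnmappedReferenceFilter(CCDLError):
    """A reference-type attribute filter was used where the mapping does not
    declare a reference target."""


class MissingLeafSet(CCDLError):
    """evaluate_tree received no patient set for one of the plan's leaves."""


class ConfigInvalid(CCDLError):
    """A generator or CLI configuration file is invalid."""


class TranslationError(CCDLError):
    """Aggregate of per-leaf translation failures."""

    def __init__(self, failures: list[tuple[str, Exception]]) -> None:
        lines = [f"{path}: {exc}" for path, exc in failures]
        super().__init__("translation failed for {} leaf/leaves:\n{}".format(len(failures), "\n".join(lines)))
        self.failures = failures
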