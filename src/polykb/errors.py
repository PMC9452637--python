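"""Machine-readable engine errors.

Every error carries a stable ``code`` string so callers (the CLI, scripted
curation sessions) can branch on failures without parsing messages.
"""

from __future__ import annotations


class KBError(Exception):
    """Base class for all knowledgebase engine errors."""

    code: str = "kb-error"

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {super().__str__()}"


class DuplicateTableName(KBError):
    code = "duplicate-table-name"


class InvalidIdentifier(KBError):
    code = "invalid-identifier"


class ReservedFieldName(KBError):
    code = "reserved-field-name"


class DuplicateFieldName(KBError):
    code = "duplicate-field-name"


class UnknownTable(KBError):
    code = "unknown-table"


class UnknownField(KBError):
    code = "unknown-field"


class UnknownRecord(KBError):
    code = "unknown-record"


class TypeMismatch(KBError):
    code = "type-mismatch"


class ReferenceAtInsert(KBError):
    code = "reference-at-insert"


class UnknownSource(KBError):
    code = "unknown-source"


class NotAReferenceField(KBError):
    code = "not-a-reference-field"


class UnknownTargetTable(KBError):
    code = "unknown-target-table"


class UnknownTargetRecord(KBError):
    code = "unknown-target-record"


class TargetTableNotLinkable(KBError):
    code = "target-table-not-linkable"


class RestrictedByInboundRefs(KBError):
    code = "restricted-by-inbound-refs"

    def __init__(self, message: str, blockers=(), **context):
        super().__init__(message, **context)
        # (table, id, field) triples that point at the record being deleted
        self.blockers = list(blockers)


class InvalidConstraint(KBError):
    code = "invalid-constraint"


class UncleanKB(KBError):
    code = "unclean-kb"


class MalformedDocument(KBError):
    code = "malformed-document"


class VersionUnsupported(KBError):
    code = "version-unsupported"


class UnrecognizedSchemaShape(KBError):
    code = "unrecognized-schema-shape"
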