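"""Whole-knowledgebase and per-value integrity checking.

Violations are returned as values, never raised: curation tools need a
full report, not a first-failure abort.  Null passes every constraint
except ``required`` — a blank reference is a legitimate intermediate
state of knowledge entry, not an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Any, Optional

from .model import (
    FieldDef,
    FieldType,
    Knowledgebase,
    PolymorphicRef,
    check_scalar_type,
)


class ViolationCode(str, Enum):
    DANGLING_REF_TABLE = "DANGLING_REF_TABLE"
    DANGLING_REF_RECORD = "DANGLING_REF_RECORD"
    REQUIRED_NULL = "REQUIRED_NULL"
    TYPE_MISMATCH = "TYPE_MISMATCH"
    ENUM_VIOLATION = "ENUM_VIOLATION"
    PATTERN_VIOLATION = "PATTERN_VIOLATION"
    RANGE_VIOLATION = "RANGE_VIOLATION"
    LENGTH_VIOLATION = "LENGTH_VIOLATION"
    UNIQUE_VIOLATION = "UNIQUE_VIOLATION"
    TARGET_NOT_LINKABLE = "TARGET_NOT_LINKABLE"


@dataclass
class Violation:
    """One integrity or constraint failure, with a machine-readable code."""

    code: ViolationCode
    table: Optional[str] = None
    record_id: Optional[int] = None
    field: Optional[str] = None
    message: str = ""

    def locator(self) -> str:
        parts = [self.table or "?"]
        if self.record_id is not None:
            parts[-1] += f"#{self.record_id}"
        if self.field is not None:
            parts.append(self.field)
        return ".".join(parts)


def validate_value(field: FieldDef, value: Any) -> list[Violation]:
    """Check one value against its field's type and declared constraints."""
    out: list[Violation] = []
    if value is None:
        for c in field.constraints:
            if c.kind == "required":
                out.append(
                    Violation(
                        ViolationCode.REQUIRED_NULL,
                        field=field.name,
                        message=f"field {field.name!r} is required but null",
                    )
                )
        return out
    if not check_scalar_type(field.type, value):
        out.append(
            Violation(
                ViolationCode.TYPE_MISMATCH,
                field=field.name,
                message=(
                    f"value {value!r} does not match type {field.type.value} "
                    f"of field {field.name!r}"
                ),
            )
        )
        return out
    for c in field.constraints:
        if c.kind == "enum_values" and value not in c.parameters:
            out.append(
                Violation(
                    ViolationCode.ENUM_VIOLATION,
                    field=field.name,
                    message=f"{value!r} not in enum {list(c.parameters)!r}",
                )
            )
        elif c.kind == "pattern" and not re.fullmatch(c.parameters, value):
            out.append(
                Violation(
                    ViolationCode.PATTERN_VIOLATION,
                    field=field.name,
                    message=f"{value!r} does not match pattern {c.parameters!r}",
                )
            )
        elif c.kind == "min_value" and value < c.parameters:
            out.append(
                Violation(
                    ViolationCode.RANGE_VIOLATION,
                    field=field.name,
                    message=f"{value!r} below minimum {c.parameters!r}",
                )
            )
        elif c.kind == "max_value" and value > c.parameters:
            out.append(
                Violation(
                    ViolationCode.RANGE_VIOLATION,
                    field=field.name,
                    message=f"{value!r} above maximum {c.parameters!r}",
                )
            )
        elif c.kind == "max_length" and len(value) > c.parameters:
            out.append(
                Violation(
                    ViolationCode.LENGTH_VIOLATION,
                    field=field.name,
                    message=f"length {len(value)} exceeds {c.parameters}",
                )
            )
    return out


def _check_reference(kb: Knowledgebase, ref: PolymorphicRef) -> Optional[ViolationCode]:
    td = kb.tables.get(ref.target_table.lower())
    if td is None:
        return ViolationCode.DANGLING_REF_TABLE
    if not td.linkable:
        return ViolationCode.TARGET_NOT_LINKABLE
    if not any(r.id == ref.target_id for r in kb.records[td.name.lower()]):
        return ViolationCode.DANGLING_REF_RECORD
    return None


def validate_kb(kb: Knowledgebase) -> list[Violation]:
    """Full integrity report in deterministic (table, id, field) order.

    Per table, in creation order: per-record per-field value violations
    and dangling/unlinkable reference checks, then one UNIQUE_VIOLATION
    per duplicated value beyond the first for every ``unique`` field.
    """
    out: list[Violation] = []
    for td in kb.tables.values():
        recs = kb.records[td.name.lower()]
        for rec in recs:
            for fd in td.user_fields():
                value = rec.values.get(fd.name)
                for v in validate_value(fd, value):
                    v.table = td.name
                    v.record_id = rec.id
                    out.append(v)
                if isinstance(value, PolymorphicRef):
                    code = _check_reference(kb, value)
                    if code is not None:
                        out.append(
                            Violation(
                                code,
                                table=td.name,
                                record_id=rec.id,
                                field=fd.name,
                                message=(
                                    f"reference to {value.target_table}"
                                    f"#{value.target_id} cannot be resolved"
                                    if code is not ViolationCode.TARGET_NOT_LINKABLE
                                    else f"table {value.target_table!r} is not a "
                                    "valid reference target"
                                ),
                            )
                        )
        for fd in td.user_fields():
            if not any(c.kind == "unique" for c in fd.constraints):
                continue
            seen: dict[Any, int] = {}
            for rec in recs:
                value = rec.values.get(fd.name)
                if value is None:  # nulls never conflict
                    continue
                try:
                    key = value
                    if key in seen:
                        out.append(
                            Violation(
                                ViolationCode.UNIQUE_VIOLATION,
                                table=td.name,
                                record_id=rec.id,
                                field=fd.name,
                                message=(
                                    f"duplicate value {value!r}; first seen in "
                                    f"{td.name}#{seen[key]}"
                                ),
                            )
                        )
                    else:
                        seen[key] = rec.id
                except TypeError:  # unhashable (ill-typed) values: skip
                    continue
    return out
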