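"""Runtime-defined schema (meta-database) and record storage (entity base).

The engine keeps two stores: table definitions created at run time, and
records linked by *polymorphic references* — a stored pair
``(table name, record id)`` that may point at a record in any table,
unlike a relational foreign key which is bound to one target table when
the schema is written.  Schema curation and content entry may be
interleaved in any order; a reference field is left blank at insert time
and wired up afterwards with :meth:`Knowledgebase.set_reference`.

Identifiers (table and field names) are case-insensitive for uniqueness
but case-preserving for display.  Every table gets a system-assigned
integer primary key named ``id`` that starts at 1, increments by 1 and is
never reused, even after deletion.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field as dc_field
from datetime import date
from enum import Enum
from typing import Any, Iterable, Optional

from . import errors

IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
SYSTEM_KEY_NAME = "id"


class FieldType(str, Enum):
    """Value types a field may hold.

    ``REFERENCE`` is the only type whose values are :class:`PolymorphicRef`
    pairs; all others carry scalars.  ``DATE`` is ISO-8601 text
    (``YYYY-MM-DD``); ``DECIMAL`` accepts ints and floats.
    """

    TEXT = "TEXT"
    INTEGER = "INTEGER"
    DECIMAL = "DECIMAL"
    BOOLEAN = "BOOLEAN"
    DATE = "DATE"
    ENUM = "ENUM"
    REFERENCE = "REFERENCE"


#: constraint kinds admissible per field type (``required`` is universal)
_CONSTRAINT_APPLICABILITY = {
    "required": set(FieldType),
    "unique": set(FieldType) - {FieldType.REFERENCE},
    "enum_values": {FieldType.ENUM, FieldType.TEXT},
    "pattern": {FieldType.TEXT, FieldType.DATE},
    "min_value": {FieldType.INTEGER, FieldType.DECIMAL},
    "max_value": {FieldType.INTEGER, FieldType.DECIMAL},
    "max_length": {FieldType.TEXT, FieldType.ENUM},
}


@dataclass(frozen=True)
class PolymorphicRef:
    """A pair of identifiers: one names a table, the other a record in it."""

    target_table: str
    target_id: int

    def __post_init__(self):
        if not isinstance(self.target_id, int) or isinstance(self.target_id, bool) or self.target_id < 1:
            raise errors.TypeMismatch(
                f"reference id must be a positive integer, got {self.target_id!r}"
            )


@dataclass
class FieldConstraint:
    """One declared constraint on a field's values.

    kind           parameters
    -------------  -----------------------------------
    required       none
    unique         none
    enum_values    list of admissible values
    pattern        regular expression (full match)
    min_value      numeric lower bound (inclusive)
    max_value      numeric upper bound (inclusive)
    max_length     maximum string length (integer)
    """

    kind: str
    parameters: Any = None

    def check_applicable(self, ftype: FieldType) -> None:
        allowed = _CONSTRAINT_APPLICABILITY.get(self.kind)
        if allowed is None:
            raise errors.InvalidConstraint(f"unknown constraint kind {self.kind!r}")
        if ftype not in allowed:
            raise errors.InvalidConstraint(
                f"constraint {self.kind!r} not applicable to type {ftype.value}"
            )
        if self.kind == "enum_values" and not (
            isinstance(self.parameters, (list, tuple)) and self.parameters
        ):
            raise errors.InvalidConstraint("enum_values needs a nonempty value list")
        if self.kind == "pattern":
            try:
                re.compile(self.parameters)
            except (re.error, TypeError) as exc:
                raise errors.InvalidConstraint(f"bad pattern: {exc}") from exc
        if self.kind in ("min_value", "max_value") and not isinstance(
            self.parameters, (int, float)
        ):
            raise errors.InvalidConstraint(f"{self.kind} needs a numeric bound")
        if self.kind == "max_length" and not (
            isinstance(self.parameters, int) and self.parameters >= 0
        ):
            raise errors.InvalidConstraint("max_length needs a non-negative integer")


@dataclass
class FieldDef:
    """A named, typed, annotated, constrained field of a table."""

    name: str
    type: FieldType
    annotation: str = ""
    constraints: list[FieldConstraint] = dc_field(default_factory=list)
    system_key: bool = False

    def __post_init__(self):
        if isinstance(self.type, str):
            self.type = FieldType(self.type)

    def validate_definition(self) -> None:
        if not IDENTIFIER_RE.match(self.name or ""):
            raise errors.InvalidIdentifier(f"invalid field name {self.name!r}")
        if self.system_key:
            if self.type is not FieldType.INTEGER or self.constraints:
                raise errors.InvalidIdentifier(
                    "system key must be INTEGER with no user constraints"
                )
        else:
            if self.name.lower() == SYSTEM_KEY_NAME:
                raise errors.ReservedFieldName(
                    f"{SYSTEM_KEY_NAME!r} is reserved for the system key"
                )
            for c in self.constraints:
                c.check_applicable(self.type)
            if self.type is FieldType.REFERENCE:
                for c in self.constraints:
                    if c.kind != "required":
                        raise errors.InvalidConstraint(
                            "REFERENCE fields admit only the 'required' constraint"
                        )


def system_key_field() -> FieldDef:
    return FieldDef(name=SYSTEM_KEY_NAME, type=FieldType.INTEGER, system_key=True)


@dataclass
class TableDef:
    """A runtime-defined table: the system key field first, then user fields.

    ``linkable`` records whether the table satisfies the single-unique-key
    rule (exactly one unique record key); always true for tables this
    engine creates, but imported relational dumps may carry extra unique
    columns and then must not be the target of a polymorphic reference.
    """

    name: str
    fields: list[FieldDef] = dc_field(default_factory=list)
    linkable: bool = True

    def user_fields(self) -> list[FieldDef]:
        return [f for f in self.fields if not f.system_key]

    def get_field(self, name: str) -> Optional[FieldDef]:
        low = name.lower()
        for f in self.fields:
            if f.name.lower() == low:
                return f
        return None


@dataclass
class Record:
    """A row in the entity base.

    ``values`` maps every non-system field name (display case) to a
    scalar, a :class:`PolymorphicRef`, or ``None``.  ``id`` is
    system-assigned, immutable, unique within its table.
    """

    table: str
    id: int
    values: dict[str, Any] = dc_field(default_factory=dict)


@dataclass
class MigrationEntry:
    """One append-only audit entry; replaying the log rebuilds the kb."""

    seq: int
    op: str  # CREATE_TABLE | ADD_FIELD | INSERT | SET_REF | CLEAR_REF | DELETE
    details: dict[str, Any]


def check_scalar_type(ftype: FieldType, value: Any) -> bool:
    """True iff ``value`` is a well-typed non-null scalar for ``ftype``."""
    if ftype is FieldType.TEXT or ftype is FieldType.ENUM:
        return isinstance(value, str)
    if ftype is FieldType.INTEGER:
        return isinstance(value, int) and not isinstance(value, bool)
    if ftype is FieldType.DECIMAL:
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if ftype is FieldType.BOOLEAN:
        return isinstance(value, bool)
    if ftype is FieldType.DATE:
        if not isinstance(value, str):
            return False
        try:
            date.fromisoformat(value)
            return True
        except ValueError:
            return False
    if ftype is FieldType.REFERENCE:
        return isinstance(value, PolymorphicRef)
    return False  # pragma: no cover


class Knowledgebase:
    """Schema store + record store + id counters + migration log.

    All lookups are case-insensitive; all mutating operations validate
    their preconditions before touching any state, so a raised error
    leaves the knowledgebase exactly as it was.
    """

    def __init__(self) -> None:
        # keyed by lowercase name; values hold display-case names
        self.tables: dict[str, TableDef] = {}
        self.records: dict[str, list[Record]] = {}
        self.counters: dict[str, int] = {}
        self.migration_log: list[MigrationEntry] = []

    # -- internal helpers -------------------------------------------------

    def _log(self, op: str, details: dict[str, Any]) -> None:
        self.migration_log.append(
            MigrationEntry(seq=len(self.migration_log) + 1, op=op, details=details)
        )

    def _table(self, name: str) -> TableDef:
        td = self.tables.get(name.lower())
        if td is None:
            raise errors.UnknownTable(f"no table named {name!r}")
        return td

    def _record(self, table: str, record_id: int) -> Record:
        td = self._table(table)
        for rec in self.records[td.name.lower()]:
            if rec.id == record_id:
                return rec
        raise errors.UnknownRecord(f"no record {td.name}#{record_id}")

    # -- introspection ----------------------------------------------------

    def table_names(self) -> list[str]:
        """Display-case table names in creation order."""
        return [td.name for td in self.tables.values()]

    def has_table(self, name: str) -> bool:
        return name.lower() in self.tables

    def get_table(self, name: str) -> TableDef:
        return self._table(name)

    def get_record(self, table: str, record_id: int) -> Record:
        return self._record(table, record_id)

    def iter_records(self, table: Optional[str] = None) -> Iterable[Record]:
        if table is not None:
            yield from self.records[self._table(table).name.lower()]
            return
        for key in self.tables:
            yield from self.records[key]

    def record_count(self) -> int:
        return sum(len(v) for v in self.records.values())

    def copy(self) -> "Knowledgebase":
        return copy.deepcopy(self)

    # -- schema curation --------------------------------------------------

    def create_table(self, name: str, fields: Iterable[FieldDef] = ()) -> TableDef:
        """Register a new table; the system key ``id`` is prepended."""
        fields = list(fields)
        if not IDENTIFIER_RE.match(name or ""):
            raise errors.InvalidIdentifier(f"invalid table name {name!r}")
        if name.lower() in self.tables:
            raise errors.DuplicateTableName(f"table {name!r} already exists")
        seen: set[str] = set()
        for fd in fields:
            if fd.system_key:
                raise errors.ReservedFieldName("system key is created automatically")
            fd.validate_definition()
            if fd.name.lower() in seen:
                raise errors.DuplicateFieldName(
                    f"duplicate field {fd.name!r} in table {name!r}"
                )
            seen.add(fd.name.lower())
        td = TableDef(name=name, fields=[system_key_field(), *fields])
        key = name.lower()
        self.tables[key] = td
        self.records[key] = []
        self.counters[key] = 0
        self._log(
            "CREATE_TABLE",
            {"table": name, "fields": [_field_to_spec(f) for f in fields]},
        )
        return td

    def add_field(self, table: str, field: FieldDef) -> TableDef:
        """Append a field; existing records are back-filled with null."""
        td = self._table(table)
        if field.system_key:
            raise errors.ReservedFieldName("system key is created automatically")
        field.validate_definition()
        if td.get_field(field.name) is not None:
            raise errors.DuplicateFieldName(
                f"field {field.name!r} already exists in table {td.name!r}"
            )
        td.fields.append(field)
        for rec in self.records[td.name.lower()]:
            rec.values[field.name] = None
        self._log("ADD_FIELD", {"table": td.name, "field": _field_to_spec(field)})
        return td

    # -- content entry ----------------------------------------------------

    def insert_record(self, table: str, values: Optional[dict[str, Any]] = None) -> Record:
        """Insert a row; reference fields stay blank and are linked later.

        Only type compatibility is checked here; declared constraints
        (required, enum, range, ...) are enforced by batch validation so
        that half-entered knowledge is representable.
        """
        values = dict(values or {})
        td = self._table(table)
        stored: dict[str, Any] = {}
        by_lower = {f.name.lower(): f for f in td.user_fields()}
        for key, val in values.items():
            fd = by_lower.get(key.lower())
            if fd is None:
                if key.lower() == SYSTEM_KEY_NAME:
                    raise errors.ReservedFieldName("the system key is auto-assigned")
                raise errors.UnknownField(f"table {td.name!r} has no field {key!r}")
            if fd.type is FieldType.REFERENCE:
                if val is not None:
                    raise errors.ReferenceAtInsert(
                        f"reference field {fd.name!r} must be linked with "
                        "set_reference, not supplied at insert"
                    )
            elif val is not None and not check_scalar_type(fd.type, val):
                raise errors.TypeMismatch(
                    f"value {val!r} is not valid for {fd.type.value} field {fd.name!r}"
                )
            stored[fd.name] = val
        full = {f.name: stored.get(f.name) for f in td.user_fields()}
        key = td.name.lower()
        self.counters[key] += 1
        rec = Record(table=td.name, id=self.counters[key], values=full)
        self.records[key].append(rec)
        self._log("INSERT", {"table": td.name, "id": rec.id, "values": dict(values)})
        return rec

    def set_reference(
        self,
        table: str,
        record_id: int,
        field: str,
        target_table: str,
        target_id: int,
    ) -> Record:
        """Wire a reference field to exactly one record in one table."""
        try:
            rec = self._record(table, record_id)
        except errors.KBError as exc:
            raise errors.UnknownSource(str(exc)) from exc
        fd = self.tables[rec.table.lower()].get_field(field)
        if fd is None or fd.system_key or fd.type is not FieldType.REFERENCE:
            raise errors.NotAReferenceField(
                f"{rec.table}.{field} is not a REFERENCE field"
            )
        target_td = self.tables.get(target_table.lower())
        if target_td is None:
            raise errors.UnknownTargetTable(f"no table named {target_table!r}")
        if not target_td.linkable:
            raise errors.TargetTableNotLinkable(
                f"table {target_td.name!r} lacks a single unique key"
            )
        if not any(r.id == target_id for r in self.records[target_td.name.lower()]):
            raise errors.UnknownTargetRecord(f"no record {target_td.name}#{target_id}")
        rec.values[fd.name] = PolymorphicRef(target_td.name, target_id)
        self._log(
            "SET_REF",
            {
                "table": rec.table,
                "id": rec.id,
                "field": fd.name,
                "target_table": target_td.name,
                "target_id": target_id,
            },
        )
        return rec

    def clear_reference(self, table: str, record_id: int, field: str) -> Record:
        try:
            rec = self._record(table, record_id)
        except errors.KBError as exc:
            raise errors.UnknownSource(str(exc)) from exc
        fd = self.tables[rec.table.lower()].get_field(field)
        if fd is None or fd.system_key or fd.type is not FieldType.REFERENCE:
            raise errors.NotAReferenceField(
                f"{rec.table}.{field} is not a REFERENCE field"
            )
        rec.values[fd.name] = None
        self._log("CLEAR_REF", {"table": rec.table, "id": rec.id, "field": fd.name})
        return rec

    def resolve_reference(self, ref: PolymorphicRef) -> Record:
        """Return the unique record a reference points at.

        Dangling references raise distinct errors so validation can
        classify them; resolution never silently returns null.
        """
        td = self.tables.get(ref.target_table.lower())
        if td is None:
            raise errors.UnknownTargetTable(f"no table named {ref.target_table!r}")
        for rec in self.records[td.name.lower()]:
            if rec.id == ref.target_id:
                return rec
        raise errors.UnknownTargetRecord(f"no record {td.name}#{ref.target_id}")

    def inbound_references(self, table: str, record_id: int) -> list[tuple[str, int, str]]:
        """All (table, id, field) locations holding a ref to the given record."""
        td = self._table(table)
        hits = []
        for rec in self.iter_records():
            for fname, val in rec.values.items():
                if (
                    isinstance(val, PolymorphicRef)
                    and val.target_table.lower() == td.name.lower()
                    and val.target_id == record_id
                ):
                    hits.append((rec.table, rec.id, fname))
        return hits

    def delete_record(
        self, table: str, record_id: int, policy: str = "restrict"
    ) -> list[tuple[str, int, str]]:
        """Remove a record.

        ``restrict`` refuses if any inbound reference exists (listing the
        blockers); ``nullify`` blanks every inbound reference first.  The
        freed id is never reissued.
        """
        if policy not in ("restrict", "nullify"):
            raise ValueError(f"unknown deletion policy {policy!r}")
        rec = self._record(table, record_id)
        inbound = self.inbound_references(rec.table, rec.id)
        if policy == "restrict" and inbound:
            raise errors.RestrictedByInboundRefs(
                f"{rec.table}#{rec.id} is referenced by "
                + ", ".join(f"{t}#{i}.{f}" for t, i, f in inbound),
                blockers=inbound,
            )
        for t, i, f in inbound:
            self._record(t, i).values[f] = None
        key = rec.table.lower()
        self.records[key] = [r for r in self.records[key] if r.id != rec.id]
        self._log(
            "DELETE",
            {
                "table": rec.table,
                "id": rec.id,
                "policy": policy,
                "nullified": [list(x) for x in inbound],
            },
        )
        return inbound


def _field_to_spec(fd: FieldDef) -> dict[str, Any]:
    """Plain-data rendering of a field definition (for logs and documents)."""
    return {
        "name": fd.name,
        "type": fd.type.value,
        "annotation": fd.annotation,
        "constraints": [
            {"kind": c.kind, "parameters": c.parameters} for c in fd.constraints
        ],
        "system_key": fd.system_key,
    }


def _field_from_spec(spec: dict[str, Any]) -> FieldDef:
    return FieldDef(
        name=spec["name"],
        type=FieldType(spec["type"]),
        annotation=spec.get("annotation", ""),
        constraints=[
            FieldConstraint(kind=c["kind"], parameters=c.get("parameters"))
            for c in spec.get("constraints", [])
        ],
        system_key=bool(spec.get("system_key", False)),
    )


def replay_log(entries: Iterable[MigrationEntry]) -> Knowledgebase:
    """Rebuild a knowledgebase by replaying its migration log from empty."""
    kb = Knowledgebase()
    for entry in entries:
        d = entry.details
        if entry.op == "CREATE_TABLE":
            kb.create_table(d["table"], [_field_from_spec(s) for s in d["fields"]])
        elif entry.op == "ADD_FIELD":
            kb.add_field(d["table"], _field_from_spec(d["field"]))
        elif entry.op == "INSERT":
            rec = kb.insert_record(d["table"], d["values"])
            if rec.id != d["id"]:  # pragma: no cover - defensive
                raise errors.KBError(
                    f"replay assigned id {rec.id}, log recorded {d['id']}"
                )
        elif entry.op == "SET_REF":
            kb.set_reference(
                d["table"], d["id"], d["field"], d["target_table"], d["target_id"]
            )
        elif entry.op == "CLEAR_REF":
            kb.clear_reference(d["table"], d["id"], d["field"])
        elif entry.op == "DELETE":
            kb.delete_record(d["table"], d["id"], policy=d["policy"])
        else:  # pragma: no cover - defensive
            raise errors.KBError(f"unknown log op {entry.op!r}")
    return kb
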