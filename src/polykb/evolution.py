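"""Schema evolution by table addition and reference rewiring.

The engine's central property: a new knowledge category enters the
knowledgebase as a *new* table plus rewired polymorphic references, with
zero modification of any pre-existing table's structure or constraints
and zero changes to pre-existing record values outside the explicitly
rewired reference fields.  :func:`extend_with_table` applies such an
extension atomically and verifies the no-touch property itself before
committing; :func:`schema_fingerprint` is the instrument that makes the
property auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Any, Iterable, Optional

from . import errors
from .model import FieldDef, Knowledgebase, _field_to_spec


def schema_fingerprint(kb: Knowledgebase, table: str) -> str:
    """Canonical text rendering of one table's full structural definition.

    Two tables have equal fingerprints iff their definitions (name,
    field order, types, annotations, constraints, linkability) are
    structurally identical.  Record data never affects the fingerprint.
    """
    td = kb.get_table(table)
    payload = {
        "name": td.name,
        "linkable": td.linkable,
        "fields": [_field_to_spec(f) for f in td.fields],
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


@dataclass
class Rewire:
    """One reference move: (table, record_id, field) now points at target."""

    table: str
    record_id: int
    field: str
    target_table: str
    target_id: int


@dataclass
class ExtensionSpec:
    """Declarative description of one schema extension."""

    name: str
    fields: list[FieldDef] = dc_field(default_factory=list)
    records: list[dict[str, Any]] = dc_field(default_factory=list)
    rewires: list[Rewire] = dc_field(default_factory=list)


@dataclass
class ExtensionReport:
    table: str
    records_inserted: int
    rewires_applied: int
    preexisting_tables: list[str]


def extend_with_table(
    kb: Knowledgebase,
    new_table: str | ExtensionSpec,
    fields: Optional[Iterable[FieldDef]] = None,
    records: Iterable[dict[str, Any]] = (),
    rewires: Iterable[Rewire | tuple] = (),
) -> ExtensionReport:
    """Atomically add a table, populate it, and rewire references into it.

    Either pass an :class:`ExtensionSpec`, or the table name plus its
    fields/records/rewires.  Any underlying failure rolls the
    knowledgebase back to its pre-call state; on success an internal
    check asserts that every pre-existing table's fingerprint and every
    pre-existing record value outside the rewired fields is unchanged.
    """
    if isinstance(new_table, ExtensionSpec):
        spec = new_table
    else:
        spec = ExtensionSpec(
            name=new_table,
            fields=list(fields or []),
            records=list(records),
            rewires=[r if isinstance(r, Rewire) else Rewire(*r) for r in rewires],
        )
    pre_tables = kb.table_names()
    pre_fps = {t: schema_fingerprint(kb, t) for t in pre_tables}
    pre_values = {
        (rec.table, rec.id): dict(rec.values) for rec in kb.iter_records()
    }
    rewired_fields = {(r.table.lower(), r.record_id, r.field.lower()) for r in spec.rewires}
    snapshot = kb.copy()
    try:
        td = kb.create_table(spec.name, spec.fields)
        inserted = 0
        for values in spec.records:
            kb.insert_record(td.name, values)
            inserted += 1
        applied = 0
        for rw in spec.rewires:
            kb.set_reference(
                rw.table, rw.record_id, rw.field, rw.target_table, rw.target_id
            )
            applied += 1
        _assert_no_touch(kb, pre_fps, pre_values, rewired_fields)
    except Exception:
        # full rollback: restore the pre-call state in place
        kb.tables = snapshot.tables
        kb.records = snapshot.records
        kb.counters = snapshot.counters
        kb.migration_log = snapshot.migration_log
        raise
    return ExtensionReport(
        table=td.name,
        records_inserted=inserted,
        rewires_applied=applied,
        preexisting_tables=pre_tables,
    )


def _assert_no_touch(kb, pre_fps, pre_values, rewired_fields) -> None:
    for t, fp in pre_fps.items():
        if schema_fingerprint(kb, t) != fp:  # pragma: no cover - defensive
            raise errors.KBError(f"extension modified pre-existing table {t!r}")
    for (table, rid), old in pre_values.items():
        rec = kb.get_record(table, rid)
        for fname, old_val in old.items():
            if (table.lower(), rid, fname.lower()) in rewired_fields:
                continue
            if rec.values.get(fname) != old_val:  # pragma: no cover - defensive
                raise errors.KBError(
                    f"extension modified {table}#{rid}.{fname} outside rewires"
                )


def diff_after_extension(
    pre: Knowledgebase, post: Knowledgebase
) -> dict[str, Any]:
    """Independent pre/post comparison of an extension's effect.

    Returns counts of pre-existing tables whose fingerprints changed and
    pre-existing record fields whose values changed, plus the changed
    field locations.  Used as the external cross-check of the internal
    no-touch assertion.
    """
    changed_tables = []
    for t in pre.table_names():
        if schema_fingerprint(pre, t) != schema_fingerprint(post, t):
            changed_tables.append(t)
    changed_fields: list[tuple[str, int, str]] = []
    for rec in pre.iter_records():
        post_rec = post.get_record(rec.table, rec.id)
        for fname, val in rec.values.items():
            if post_rec.values.get(fname) != val:
                changed_fields.append((rec.table, rec.id, fname))
    return {
        "tables_changed": changed_tables,
        "fields_changed": changed_fields,
        "n_tables_changed": len(changed_tables),
        "n_fields_changed": len(changed_fields),
    }


def extension_from_dict(raw: dict[str, Any]) -> ExtensionSpec:
    """Parse the declarative extension document (mind-map dialect).

    Expected shape::

        table:
          name: ITPATherapy
          fields: [{name: ..., type: ..., annotation: ..., constraints: [...]}]
        records:
          - {description: "..."}
        rewires:
          - {table: Judgement, id: 3, field: Next, target_table: ITPATherapy, target_id: 1}
    """
    from .model import _field_from_spec

    try:
        tspec = raw["table"]
        name = tspec["name"]
        fields = [_field_from_spec(s) for s in tspec.get("fields", [])]
    except (KeyError, TypeError, ValueError) as exc:
        raise errors.MalformedDocument(f"bad extension table spec: {exc}") from exc
    records = list(raw.get("records", []) or [])
    rewires = []
    for r in raw.get("rewires", []) or []:
        try:
            rewires.append(
                Rewire(
                    table=r["table"],
                    record_id=r["id"],
                    field=r["field"],
                    target_table=r["target_table"],
                    target_id=r["target_id"],
                )
            )
        except (KeyError, TypeError) as exc:
            raise errors.MalformedDocument(f"bad rewire entry {r!r}") from exc
    return ExtensionSpec(name=name, fields=fields, records=records, rewires=rewires)


def extension_to_dict(spec: ExtensionSpec) -> dict[str, Any]:
    return {
        "table": {
            "name": spec.name,
            "fields": [_field_to_spec(f) for f in spec.fields],
        },
        "records": [dict(r) for r in spec.records],
        "rewires": [
            {
                "table": r.table,
                "id": r.record_id,
                "field": r.field,
                "target_table": r.target_table,
                "target_id": r.target_id,
            }
            for r in spec.rewires
        ],
    }
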