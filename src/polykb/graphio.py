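"""Mind-map face of the knowledgebase.

A knowledgebase serializes to a versioned, human-diffable YAML document
in which each node is identified by its table name and primary key and
each polymorphic reference is written as an explicit two-part locator
``{table: ..., id: ...}``.  The same document doubles as the canonical
serialization used for equality checks throughout the engine (the
migration log is an audit artifact and is deliberately excluded).

Decision flows are walked with :func:`traverse_flow`, which follows one
reference field from record to record until it goes blank, dangles, or
revisits a node (cycles are representable and reported, never an error —
re-test loops are legitimate clinical flows).  :func:`render_dot` emits
the graph in DOT for downstream layout tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Optional

import yaml

from . import errors
from .model import (
    FieldType,
    Knowledgebase,
    PolymorphicRef,
    Record,
    TableDef,
    _field_from_spec,
    _field_to_spec,
)

FORMAT_VERSION = "1.0"


@dataclass
class MindMapDocument:
    """Self-contained plain-data rendering of a knowledgebase."""

    format_version: str
    tables: list[dict[str, Any]]
    records: dict[str, list[dict[str, Any]]]
    counters: dict[str, int]

    def to_dict(self) -> dict[str, Any]:
        return {
            "format_version": self.format_version,
            "tables": self.tables,
            "records": self.records,
            "counters": self.counters,
        }


def _value_to_doc(value: Any) -> Any:
    if isinstance(value, PolymorphicRef):
        return {"table": value.target_table, "id": value.target_id}
    return value


def _value_from_doc(ftype: FieldType, value: Any, where: str) -> Any:
    if value is None:
        return None
    if ftype is FieldType.REFERENCE:
        if (
            not isinstance(value, dict)
            or set(value) != {"table", "id"}
            or not isinstance(value.get("table"), str)
        ):
            raise errors.MalformedDocument(
                f"{where}: reference must be a {{table, id}} locator, got {value!r}"
            )
        return PolymorphicRef(value["table"], value["id"])
    if isinstance(value, dict):
        raise errors.MalformedDocument(f"{where}: scalar field holds a mapping")
    return value


def to_mindmap(kb: Knowledgebase) -> MindMapDocument:
    tables = []
    records: dict[str, list[dict[str, Any]]] = {}
    counters: dict[str, int] = {}
    for td in kb.tables.values():
        tables.append(
            {
                "name": td.name,
                "linkable": td.linkable,
                "fields": [_field_to_spec(f) for f in td.fields],
            }
        )
        records[td.name] = [
            {
                "id": rec.id,
                "values": {k: _value_to_doc(v) for k, v in rec.values.items()},
            }
            for rec in kb.records[td.name.lower()]
        ]
        counters[td.name] = kb.counters[td.name.lower()]
    return MindMapDocument(
        format_version=FORMAT_VERSION,
        tables=tables,
        records=records,
        counters=counters,
    )


def canonical_text(kb: Knowledgebase) -> str:
    """Deterministic YAML serialization; byte-equal iff kbs are state-equal."""
    return dumps(to_mindmap(kb))


def dumps(doc: MindMapDocument) -> str:
    return yaml.safe_dump(
        doc.to_dict(), sort_keys=False, allow_unicode=True, default_flow_style=False
    )


def loads(text: str) -> MindMapDocument:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise errors.MalformedDocument(f"not parseable as YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise errors.MalformedDocument("document root must be a mapping")
    version = raw.get("format_version")
    if version != FORMAT_VERSION:
        raise errors.VersionUnsupported(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION!r})"
        )
    for key in ("tables", "records", "counters"):
        if key not in raw:
            raise errors.MalformedDocument(f"missing top-level section {key!r}")
    return MindMapDocument(
        format_version=version,
        tables=raw["tables"],
        records=raw["records"],
        counters=raw["counters"],
    )


def from_mindmap(
    doc: MindMapDocument | str, strict: bool = True
) -> Knowledgebase:
    """Rebuild a knowledgebase from its document form.

    In strict mode (default) a document whose references dangle or point
    at non-linkable tables is rejected as malformed, naming the offending
    reference; permissive mode loads it anyway, leaving the problems to
    ``validate_kb``.  The single-unique-key rule is re-checked on load.
    """
    from .validation import ViolationCode, validate_kb  # local: avoid cycle

    if isinstance(doc, str):
        doc = loads(doc)
    kb = Knowledgebase()
    if not isinstance(doc.tables, list):
        raise errors.MalformedDocument("'tables' must be a list")
    for tspec in doc.tables:
        name = tspec.get("name")
        if not isinstance(name, str):
            raise errors.MalformedDocument(f"table entry without a name: {tspec!r}")
        try:
            fields = [_field_from_spec(s) for s in tspec.get("fields", [])]
        except (KeyError, TypeError, ValueError) as exc:
            raise errors.MalformedDocument(
                f"table {name!r}: bad field spec ({exc})"
            ) from exc
        sys_fields = [f for f in fields if f.system_key]
        if len(sys_fields) != 1 or fields[0] is not sys_fields[0]:
            raise errors.MalformedDocument(
                f"table {name!r} must have exactly one system key, first in order"
            )
        user = [f for f in fields if not f.system_key]
        td = kb.create_table(name, user)
        td.linkable = bool(tspec.get("linkable", True))
    # record section: bypass insert_record so stored ids/counters survive
    if not isinstance(doc.records, dict):
        raise errors.MalformedDocument("'records' must be a mapping")
    for tname, recs in doc.records.items():
        if not kb.has_table(tname):
            raise errors.MalformedDocument(
                f"records for unknown table {tname!r}"
            )
        td = kb.get_table(tname)
        key = td.name.lower()
        seen_ids: set[int] = set()
        for rspec in recs or []:
            rid = rspec.get("id")
            where = f"{td.name}#{rid}"
            if not isinstance(rid, int) or rid < 1 or rid in seen_ids:
                raise errors.MalformedDocument(f"{where}: bad or duplicate id")
            seen_ids.add(rid)
            raw_values = rspec.get("values", {}) or {}
            values: dict[str, Any] = {}
            for fd in td.user_fields():
                values[fd.name] = _value_from_doc(
                    fd.type, raw_values.get(fd.name), f"{where}.{fd.name}"
                )
            extra = set(raw_values) - set(values)
            if extra:
                raise errors.MalformedDocument(
                    f"{where}: unknown fields {sorted(extra)!r}"
                )
            kb.records[key].append(Record(table=td.name, id=rid, values=values))
    if not isinstance(doc.counters, dict):
        raise errors.MalformedDocument("'counters' must be a mapping")
    for tname, count in doc.counters.items():
        if not kb.has_table(tname):
            raise errors.MalformedDocument(f"counter for unknown table {tname!r}")
        key = kb.get_table(tname).name.lower()
        max_id = max((r.id for r in kb.records[key]), default=0)
        if not isinstance(count, int) or count < max_id:
            raise errors.MalformedDocument(
                f"counter for {tname!r} is {count!r} but max id is {max_id}"
            )
        kb.counters[key] = count
    # the load above re-created tables through create_table, which logged
    # schema entries; the document is state, not history, so drop them
    kb.migration_log = []
    if strict:
        bad = [
            v
            for v in validate_kb(kb)
            if v.code
            in (
                ViolationCode.DANGLING_REF_TABLE,
                ViolationCode.DANGLING_REF_RECORD,
                ViolationCode.TARGET_NOT_LINKABLE,
            )
        ]
        if bad:
            v = bad[0]
            raise errors.MalformedDocument(
                f"unresolvable reference at {v.locator()}: {v.message} "
                f"({len(bad)} such reference(s); load with strict=False to keep)"
            )
    return kb


# -- flow traversal -------------------------------------------------------


@dataclass
class FlowPath:
    """A walked decision flow: visited (table, id) steps and why it stopped."""

    steps: list[tuple[str, int]] = dc_field(default_factory=list)
    terminated_by: str = "BLANK_REF"  # BLANK_REF | CYCLE | MISSING_TARGET


def traverse_flow(
    kb: Knowledgebase, start_table: str, start_id: int, field: str = "Next"
) -> FlowPath:
    """Follow one reference field from record to record.

    Stops when the field is blank or absent from the current table
    (``BLANK_REF``), when a reference cannot be resolved
    (``MISSING_TARGET``), or when the next step is already on the path
    (``CYCLE``).  Bounded by the record count, so always terminates.
    """
    try:
        rec: Optional[Record] = kb.get_record(start_table, start_id)
    except errors.KBError as exc:
        raise errors.UnknownSource(str(exc)) from exc
    path = FlowPath(steps=[])
    visited: set[tuple[str, int]] = set()
    while True:
        assert rec is not None
        step = (rec.table, rec.id)
        path.steps.append(step)
        visited.add((rec.table.lower(), rec.id))
        fd = kb.get_table(rec.table).get_field(field)
        if fd is None or fd.type is not FieldType.REFERENCE:
            path.terminated_by = "BLANK_REF"
            return path
        ref = rec.values.get(fd.name)
        if ref is None:
            path.terminated_by = "BLANK_REF"
            return path
        assert isinstance(ref, PolymorphicRef)
        if (ref.target_table.lower(), ref.target_id) in visited:
            path.terminated_by = "CYCLE"
            return path
        try:
            rec = kb.resolve_reference(ref)
        except errors.KBError:
            path.terminated_by = "MISSING_TARGET"
            return path


# -- DOT rendering --------------------------------------------------------


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def render_dot(kb: Knowledgebase, tables: Optional[list[str]] = None) -> str:
    """Render the entity base as a DOT digraph.

    One node per record labelled ``Table#id``, grouped per table; one
    directed edge per non-null reference, labelled with the field name.
    Output is deterministic: tables sorted by name, records by id.
    ``tables`` filters which tables are shown (edges whose endpoint is
    hidden are dropped with their nodes).
    """
    if tables is None:
        shown = {k for k in kb.tables}
    else:
        shown = set()
        for t in tables:
            shown.add(kb.get_table(t).name.lower())
    lines = ["digraph knowledgebase {", "  rankdir=LR;"]
    edge_lines: list[str] = []
    for td in sorted(kb.tables.values(), key=lambda t: t.name.lower()):
        if td.name.lower() not in shown:
            continue
        lines.append(f"  subgraph cluster_{td.name} {{")
        lines.append(f"    label={_quote(td.name)};")
        for rec in sorted(kb.records[td.name.lower()], key=lambda r: r.id):
            node = f"{td.name}#{rec.id}"
            lines.append(f"    {_quote(node)} [shape=box];")
            for fd in td.user_fields():
                val = rec.values.get(fd.name)
                if not isinstance(val, PolymorphicRef):
                    continue
                if val.target_table.lower() not in shown:
                    continue
                tgt = kb.tables.get(val.target_table.lower())
                tgt_name = tgt.name if tgt is not None else val.target_table
                edge_lines.append(
                    f"  {_quote(node)} -> {_quote(f'{tgt_name}#{val.target_id}')}"
                    f" [label={_quote(fd.name)}];"
                )
        lines.append("  }")
    lines.extend(edge_lines)
    lines.append("}")
    return "\n".join(lines) + "\n"
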