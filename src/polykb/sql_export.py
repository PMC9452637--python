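"""Relational export and re-import of a knowledgebase.

A knowledgebase exports to plain DDL+DML text (sqlite-compatible, one
statement per line) and can be reconstructed from such a dump or from a
live sqlite connection.  A polymorphic reference field ``f`` becomes the
two nullable columns ``f_table`` (text) and ``f_id`` (integer) plus a
CHECK that both are null or both non-null — the standard relational
realization of a (table, record) identifier pair.  No native FOREIGN KEY
is emitted for these columns: the relational model cannot constrain a
key whose target table varies per row, which is precisely the gap this
engine exists to fill; integrity lives in ``validate_kb`` instead.

Schema detail that executable SQL cannot carry (annotations, ``pattern``
constraints, exact field types) is written in ``-- @meta`` comment lines
that database engines ignore and the importer reads back.  Dumps lacking
those comments (foreign dumps following the same conventions) are parsed
structurally; that is the path on which the single-unique-key rule is
enforced: a table exposing more than one unique key is loaded but marked
non-linkable, and a table without a single integer primary key is
rejected as an unrecognized schema shape.
"""

from __future__ import annotations

import json
import re
import sqlite3
from typing import Any, Optional, Union

from . import errors
from .model import (
    FieldConstraint,
    FieldDef,
    FieldType,
    Knowledgebase,
    PolymorphicRef,
    Record,
    TableDef,
    _field_from_spec,
    _field_to_spec,
)
from .validation import Violation, validate_kb

#: engine type -> SQL column type (sqlite-compatible dialect)
SQL_TYPE_MAP = {
    FieldType.TEXT: "TEXT",
    FieldType.INTEGER: "INTEGER",
    FieldType.DECIMAL: "REAL",
    FieldType.BOOLEAN: "BOOLEAN",
    FieldType.DATE: "TEXT",
    FieldType.ENUM: "TEXT",
}

_SQL_TYPE_BACK = {
    "TEXT": FieldType.TEXT,
    "VARCHAR": FieldType.TEXT,
    "CHAR": FieldType.TEXT,
    "CLOB": FieldType.TEXT,
    "INTEGER": FieldType.INTEGER,
    "INT": FieldType.INTEGER,
    "BIGINT": FieldType.INTEGER,
    "SMALLINT": FieldType.INTEGER,
    "REAL": FieldType.DECIMAL,
    "DOUBLE": FieldType.DECIMAL,
    "FLOAT": FieldType.DECIMAL,
    "NUMERIC": FieldType.DECIMAL,
    "DECIMAL": FieldType.DECIMAL,
    "BOOLEAN": FieldType.BOOLEAN,
    "BOOL": FieldType.BOOLEAN,
    "DATE": FieldType.DATE,
}


def _q(ident: str) -> str:
    return '"' + ident.replace('"', '""') + '"'


def _sql_literal(ftype: FieldType, value: Any) -> str:
    if value is None:
        return "NULL"
    if ftype is FieldType.BOOLEAN:
        return "1" if value else "0"
    if ftype in (FieldType.INTEGER, FieldType.DECIMAL):
        return repr(value)
    text = str(value)
    if "\n" in text or "\r" in text:
        # the dump format is line-oriented (one statement per line)
        raise errors.KBError(
            "text values containing newlines cannot be exported to SQL dumps"
        )
    return "'" + text.replace("'", "''") + "'"


def _require_clean(kb: Knowledgebase, force: bool) -> None:
    if force:
        return
    violations = validate_kb(kb)
    if violations:
        raise errors.UncleanKB(
            f"knowledgebase has {len(violations)} violation(s); "
            "fix them or export with force=True"
        )


def _column_defs(td: TableDef) -> list[str]:
    cols = [f"{_q('id')} INTEGER PRIMARY KEY"]
    checks: list[str] = []
    for fd in td.user_fields():
        if fd.type is FieldType.REFERENCE:
            ct, ci = _q(fd.name + "_table"), _q(fd.name + "_id")
            cols.append(f"{ct} TEXT")
            cols.append(f"{ci} INTEGER")
            checks.append(f"CHECK (({ct} IS NULL) = ({ci} IS NULL))")
            continue
        parts = [f"{_q(fd.name)} {SQL_TYPE_MAP[fd.type]}"]
        for c in fd.constraints:
            if c.kind == "required":
                parts.append("NOT NULL")
            elif c.kind == "unique":
                parts.append("UNIQUE")
            elif c.kind == "enum_values":
                opts = ", ".join(_sql_literal(fd.type, v) for v in c.parameters)
                parts.append(f"CHECK ({_q(fd.name)} IN ({opts}))")
            elif c.kind == "min_value":
                parts.append(f"CHECK ({_q(fd.name)} >= {c.parameters})")
            elif c.kind == "max_value":
                parts.append(f"CHECK ({_q(fd.name)} <= {c.parameters})")
            elif c.kind == "max_length":
                parts.append(f"CHECK (length({_q(fd.name)}) <= {c.parameters})")
            # 'pattern' is not portably expressible; carried by @meta only
        cols.append(" ".join(parts))
    return cols + checks


def export_ddl(kb: Knowledgebase, dialect: str = "sqlite", force: bool = False) -> list[str]:
    """One CREATE TABLE per table, in creation order, each preceded by its
    ``-- @meta`` line; ends with a ``-- @counters`` line."""
    if dialect != "sqlite":
        raise ValueError(f"unsupported dialect {dialect!r}")
    _require_clean(kb, force)
    out: list[str] = []
    for td in kb.tables.values():
        meta = {
            "name": td.name,
            "linkable": td.linkable,
            "fields": [_field_to_spec(f) for f in td.fields],
        }
        out.append(f"-- @meta {json.dumps(meta, sort_keys=True)}")
        out.append(f"CREATE TABLE {_q(td.name)} ({', '.join(_column_defs(td))});")
    counters = {td.name: kb.counters[td.name.lower()] for td in kb.tables.values()}
    out.append(f"-- @counters {json.dumps(counters, sort_keys=True)}")
    return out


def export_dml(kb: Knowledgebase, dialect: str = "sqlite", force: bool = False) -> list[str]:
    """One INSERT per record with explicit ids and explicit NULLs, ordered
    by table creation order then id."""
    if dialect != "sqlite":
        raise ValueError(f"unsupported dialect {dialect!r}")
    _require_clean(kb, force)
    out: list[str] = []
    for td in kb.tables.values():
        names = ["id"]
        for fd in td.user_fields():
            if fd.type is FieldType.REFERENCE:
                names += [fd.name + "_table", fd.name + "_id"]
            else:
                names.append(fd.name)
        col_sql = ", ".join(_q(n) for n in names)
        for rec in sorted(kb.records[td.name.lower()], key=lambda r: r.id):
            vals = [repr(rec.id)]
            for fd in td.user_fields():
                v = rec.values.get(fd.name)
                if fd.type is FieldType.REFERENCE:
                    if isinstance(v, PolymorphicRef):
                        vals.append(_sql_literal(FieldType.TEXT, v.target_table))
                        vals.append(repr(v.target_id))
                    else:
                        vals += ["NULL", "NULL"]
                else:
                    vals.append(_sql_literal(fd.type, v))
            out.append(
                f"INSERT INTO {_q(td.name)} ({col_sql}) VALUES ({', '.join(vals)});"
            )
    return out


def export_sql(kb: Knowledgebase, dialect: str = "sqlite", force: bool = False) -> list[str]:
    """Full dump: DDL followed by DML."""
    return export_ddl(kb, dialect, force) + export_dml(kb, dialect, force)


# -- import ---------------------------------------------------------------


def _split_top_level(text: str) -> list[str]:
    """Split on commas not nested in parentheses or quotes."""
    parts, depth, buf, i = [], 0, [], 0
    in_str: Optional[str] = None
    while i < len(text):
        ch = text[i]
        if in_str:
            buf.append(ch)
            if ch == in_str:
                if i + 1 < len(text) and text[i + 1] == in_str:
                    buf.append(text[i + 1])
                    i += 1
                else:
                    in_str = None
        elif ch in "'\"":
            in_str = ch
            buf.append(ch)
        elif ch == "(":
            depth += 1
            buf.append(ch)
        elif ch == ")":
            depth -= 1
            buf.append(ch)
        elif ch == "," and depth == 0:
            parts.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
        i += 1
    if buf:
        parts.append("".join(buf).strip())
    return parts


def _unquote_ident(tok: str) -> str:
    tok = tok.strip()
    if tok.startswith('"') and tok.endswith('"'):
        return tok[1:-1].replace('""', '"')
    if tok.startswith("`") and tok.endswith("`"):
        return tok[1:-1]
    if tok.startswith("[") and tok.endswith("]"):
        return tok[1:-1]
    return tok


_CREATE_RE = re.compile(
    r"^\s*CREATE\s+TABLE\s+(?:IF\s+NOT\s+EXISTS\s+)?(\S+|\"[^\"]+\")\s*\((.*)\)\s*;?\s*$",
    re.IGNORECASE | re.DOTALL,
)
_INSERT_RE = re.compile(
    r"^\s*INSERT\s+INTO\s+(\S+|\"[^\"]+\")\s*\(([^)]*)\)\s*VALUES\s*\((.*)\)\s*;?\s*$",
    re.IGNORECASE | re.DOTALL,
)


def _parse_create_table(stmt: str) -> tuple[str, list[FieldDef], bool]:
    """Structural fallback parse: (table name, fields, linkable)."""
    m = _CREATE_RE.match(stmt)
    if not m:
        raise errors.UnrecognizedSchemaShape(f"cannot parse statement: {stmt[:80]!r}")
    tname = _unquote_ident(m.group(1))
    items = _split_top_level(m.group(2))
    columns: list[tuple[str, str, bool, bool, bool]] = []  # name, type, pk, uniq, notnull
    extra_unique = 0
    for item in items:
        upper = item.upper()
        if upper.startswith(("CHECK", "FOREIGN KEY")):
            continue
        if upper.startswith(("UNIQUE", "PRIMARY KEY")):
            extra_unique += 1  # table-level key constraint
            continue
        toks = item.split()
        if len(toks) < 2:
            raise errors.UnrecognizedSchemaShape(f"bad column def {item!r} in {tname!r}")
        cname = _unquote_ident(toks[0])
        ctype = toks[1].split("(")[0].upper()
        is_pk = "PRIMARY KEY" in upper
        is_uniq = re.search(r"\bUNIQUE\b", upper) is not None
        not_null = "NOT NULL" in upper
        columns.append((cname, ctype, is_pk, is_uniq, not_null))
    pks = [c for c in columns if c[2]]
    if len(pks) != 1 or _SQL_TYPE_BACK.get(pks[0][1]) is not FieldType.INTEGER:
        raise errors.UnrecognizedSchemaShape(
            f"table {tname!r} does not expose a single integer primary key"
        )
    n_unique_keys = 1 + extra_unique + sum(1 for c in columns if c[3] and not c[2])
    fields: list[FieldDef] = []
    i = 0
    nonpk = [c for c in columns if not c[2]]
    while i < len(nonpk):
        cname, ctype, _, _, not_null = nonpk[i]
        nxt = nonpk[i + 1] if i + 1 < len(nonpk) else None
        if (
            cname.lower().endswith("_table")
            and nxt is not None
            and nxt[0].lower() == cname[: -len("_table")].lower() + "_id"
        ):
            fields.append(FieldDef(name=cname[: -len("_table")], type=FieldType.REFERENCE))
            i += 2
            continue
        ftype = _SQL_TYPE_BACK.get(ctype, FieldType.TEXT)
        constraints = []
        if not_null:
            constraints.append(FieldConstraint("required"))
        if nonpk[i][3]:
            constraints.append(FieldConstraint("unique"))
        fields.append(FieldDef(name=cname, type=ftype, constraints=constraints))
        i += 1
    return tname, fields, n_unique_keys == 1


def _parse_literal(tok: str) -> Any:
    tok = tok.strip()
    if tok.upper() == "NULL":
        return None
    if tok.startswith("'") and tok.endswith("'"):
        return tok[1:-1].replace("''", "'")
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        raise errors.MalformedDocument(f"unparseable SQL literal {tok!r}")


def _coerce(ftype: FieldType, value: Any) -> Any:
    if value is None:
        return None
    if ftype is FieldType.BOOLEAN and isinstance(value, int):
        return bool(value)
    return value


def _table_from_meta(meta: dict[str, Any]) -> TableDef:
    fields = [_field_from_spec(s) for s in meta["fields"]]
    return TableDef(
        name=meta["name"], fields=fields, linkable=bool(meta.get("linkable", True))
    )


def import_dump(
    source: Union[str, list[str], sqlite3.Connection],
) -> tuple[Knowledgebase, list[Violation]]:
    """Reconstruct a knowledgebase from a SQL dump or live connection.

    Accepts the statement list / text produced by :func:`export_ddl` +
    :func:`export_dml`, or any dump following the same conventions, or an
    open sqlite3 connection.  Counters are restored from ``@counters``
    when present, otherwise set to each table's maximum id.  Returns the
    knowledgebase together with its ``validate_kb`` report — dangling
    references in a dump load fine and surface there.
    """
    if isinstance(source, sqlite3.Connection):
        statements = _dump_connection(source)
    elif isinstance(source, str):
        statements = [ln for ln in source.splitlines() if ln.strip()]
    else:
        statements = [s for s in source if s.strip()]

    kb = Knowledgebase()
    pending_meta: Optional[dict[str, Any]] = None
    counters: dict[str, int] = {}
    for stmt in statements:
        stripped = stmt.strip()
        if stripped.startswith("-- @meta "):
            try:
                pending_meta = json.loads(stripped[len("-- @meta ") :])
            except json.JSONDecodeError as exc:
                raise errors.MalformedDocument(f"bad @meta line: {exc}") from exc
            continue
        if stripped.startswith("-- @counters "):
            try:
                counters = json.loads(stripped[len("-- @counters ") :])
            except json.JSONDecodeError as exc:
                raise errors.MalformedDocument(f"bad @counters line: {exc}") from exc
            continue
        if stripped.startswith("--"):
            continue
        upper = stripped.upper()
        if upper.startswith("CREATE TABLE"):
            if pending_meta is not None:
                td = _table_from_meta(pending_meta)
                pending_meta = None
                if td.name.lower() in kb.tables:
                    raise errors.DuplicateTableName(f"table {td.name!r} twice in dump")
                kb.tables[td.name.lower()] = td
                kb.records[td.name.lower()] = []
                kb.counters[td.name.lower()] = 0
            else:
                tname, fields, linkable = _parse_create_table(stripped)
                td = kb.create_table(tname, [])
                td.fields = [td.fields[0], *fields]
                td.linkable = linkable
        elif upper.startswith("INSERT INTO"):
            _apply_insert(kb, stripped)
        else:
            raise errors.UnrecognizedSchemaShape(
                f"unsupported statement: {stripped[:80]!r}"
            )
    for td in kb.tables.values():
        key = td.name.lower()
        max_id = max((r.id for r in kb.records[key]), default=0)
        kb.counters[key] = max(counters.get(td.name, 0), max_id)
    kb.migration_log = []
    return kb, validate_kb(kb)


def _apply_insert(kb: Knowledgebase, stmt: str) -> None:
    m = _INSERT_RE.match(stmt)
    if not m:
        raise errors.UnrecognizedSchemaShape(f"cannot parse insert: {stmt[:80]!r}")
    tname = _unquote_ident(m.group(1))
    td = kb.tables.get(tname.lower())
    if td is None:
        raise errors.UnknownTable(f"INSERT into unknown table {tname!r}")
    cols = [_unquote_ident(c) for c in _split_top_level(m.group(2))]
    vals = [_parse_literal(v) for v in _split_top_level(m.group(3))]
    if len(cols) != len(vals):
        raise errors.MalformedDocument(f"column/value count mismatch in {stmt[:80]!r}")
    by_col = dict(zip([c.lower() for c in cols], vals))
    rid = by_col.pop("id", None)
    if not isinstance(rid, int) or rid < 1:
        raise errors.MalformedDocument(f"INSERT without a positive id: {stmt[:80]!r}")
    values: dict[str, Any] = {}
    for fd in td.user_fields():
        if fd.type is FieldType.REFERENCE:
            rt = by_col.pop(fd.name.lower() + "_table", None)
            ri = by_col.pop(fd.name.lower() + "_id", None)
            if rt is None and ri is None:
                values[fd.name] = None
            elif isinstance(rt, str) and isinstance(ri, int):
                values[fd.name] = PolymorphicRef(rt, ri)
            else:
                raise errors.MalformedDocument(
                    f"half-null reference pair for {td.name}.{fd.name} (id {rid})"
                )
        else:
            values[fd.name] = _coerce(fd.type, by_col.pop(fd.name.lower(), None))
    if by_col:
        raise errors.MalformedDocument(
            f"INSERT names unknown columns {sorted(by_col)} for table {td.name!r}"
        )
    if any(r.id == rid for r in kb.records[td.name.lower()]):
        raise errors.MalformedDocument(f"duplicate id {rid} for table {td.name!r}")
    kb.records[td.name.lower()].append(Record(table=td.name, id=rid, values=values))


def _dump_connection(conn: sqlite3.Connection) -> list[str]:
    """Render a live sqlite database in this module's dump conventions."""
    out: list[str] = []
    rows = conn.execute(
        "SELECT name, sql FROM sqlite_master WHERE type='table' "
        "AND name NOT LIKE 'sqlite_%' ORDER BY rowid"
    ).fetchall()
    for name, sql in rows:
        out.append(sql.rstrip(";") + ";")
        cols = [r[1] for r in conn.execute(f"PRAGMA table_info({_q(name)})")]
        col_sql = ", ".join(_q(c) for c in cols)
        for row in conn.execute(
            f"SELECT {col_sql} FROM {_q(name)} ORDER BY {_q(cols[0])}"
        ):
            lits = []
            for v in row:
                if v is None:
                    lits.append("NULL")
                elif isinstance(v, (int, float)):
                    lits.append(repr(v))
                else:
                    lits.append("'" + str(v).replace("'", "''") + "'")
            out.append(
                f"INSERT INTO {_q(name)} ({col_sql}) VALUES ({', '.join(lits)});"
            )
    return out


def execute_dump(statements: list[str], conn: Optional[sqlite3.Connection] = None) -> sqlite3.Connection:
    """Run a dump against sqlite (in-memory by default); returns the connection."""
    conn = conn or sqlite3.connect(":memory:")
    for stmt in statements:
        if stmt.strip().startswith("--") or not stmt.strip():
            continue
        conn.execute(stmt)
    conn.commit()
    return conn
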