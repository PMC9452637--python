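"""Seeded random knowledgebases and operation sequences.

Fuzzing instruments for the engine's integrity properties: random but
reproducible schemas, contents and operation interleavings, plus
corruption planting for checking that validation finds what it should.
Everything is driven by a caller-supplied :class:`random.Random`, so any
run is replayable from its seed.
"""

from __future__ import annotations

import random
import string
from typing import Any, Optional

from .model import FieldConstraint, FieldDef, FieldType, Knowledgebase, PolymorphicRef

_SCALAR_TYPES = [
    FieldType.TEXT,
    FieldType.INTEGER,
    FieldType.DECIMAL,
    FieldType.BOOLEAN,
    FieldType.DATE,
    FieldType.ENUM,
]


def _ident(rng: random.Random, prefix: str, used: set[str]) -> str:
    while True:
        name = prefix + "".join(rng.choices(string.ascii_lowercase, k=4))
        if name.lower() not in used:
            used.add(name.lower())
            return name


def random_scalar(rng: random.Random, ftype: FieldType) -> Any:
    if ftype is FieldType.TEXT:
        return "".join(rng.choices(string.ascii_letters + " _-", k=rng.randint(0, 12)))
    if ftype is FieldType.INTEGER:
        return rng.randint(-1000, 1000)
    if ftype is FieldType.DECIMAL:
        return rng.choice([rng.randint(-50, 50), round(rng.uniform(-50, 50), 3)])
    if ftype is FieldType.BOOLEAN:
        return rng.random() < 0.5
    if ftype is FieldType.DATE:
        return f"{rng.randint(1990, 2030):04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
    if ftype is FieldType.ENUM:
        return rng.choice(["low", "normal", "high"])
    raise ValueError(ftype)  # pragma: no cover


def random_field(rng: random.Random, used: set[str], allow_reference: bool = True) -> FieldDef:
    if allow_reference and rng.random() < 0.35:
        return FieldDef(_ident(rng, "ref_", used), FieldType.REFERENCE)
    ftype = rng.choice(_SCALAR_TYPES)
    constraints = []
    if ftype is FieldType.ENUM:
        constraints.append(FieldConstraint("enum_values", ["low", "normal", "high"]))
    return FieldDef(_ident(rng, "f_", used), ftype, constraints=constraints)


def random_kb(
    rng: random.Random,
    max_tables: int = 4,
    max_fields: int = 4,
    max_records: int = 6,
    link_probability: float = 0.6,
) -> Knowledgebase:
    """A clean random knowledgebase built purely through the mutation API."""
    kb = Knowledgebase()
    used_tables: set[str] = set()
    for _ in range(rng.randint(1, max_tables)):
        used_fields: set[str] = set()
        fields = [random_field(rng, used_fields) for _ in range(rng.randint(0, max_fields))]
        kb.create_table(_ident(rng, "T_", used_tables), fields)
    tables = kb.table_names()
    for tname in tables:
        td = kb.get_table(tname)
        for _ in range(rng.randint(0, max_records)):
            values = {}
            for fd in td.user_fields():
                if fd.type is FieldType.REFERENCE:
                    continue
                if rng.random() < 0.8:
                    values[fd.name] = random_scalar(rng, fd.type)
            kb.insert_record(tname, values)
    # wire references, including self-table and self-record links
    for tname in tables:
        td = kb.get_table(tname)
        for rec in list(kb.iter_records(tname)):
            for fd in td.user_fields():
                if fd.type is not FieldType.REFERENCE:
                    continue
                if rng.random() >= link_probability:
                    continue
                target_table = rng.choice(tables)
                targets = [r.id for r in kb.iter_records(target_table)]
                if not targets:
                    continue
                kb.set_reference(
                    tname, rec.id, fd.name, target_table, rng.choice(targets)
                )
    return kb


def random_operation(rng: random.Random, kb: Knowledgebase) -> str:
    """Apply one random mutation through the public interface.

    Returns the name of the operation performed (for reporting).  Picks
    arguments that satisfy preconditions, so any raised error is an
    engine bug.
    """
    ops = ["create_table", "add_field", "insert_record", "set_reference", "delete_record"]
    weights = [1, 1, 4, 4, 2]
    tables = kb.table_names()
    while True:
        op = rng.choices(ops, weights)[0]
        if op == "create_table":
            used = {t.lower() for t in tables}
            fields_used: set[str] = set()
            kb.create_table(
                _ident(rng, "T_", used),
                [random_field(rng, fields_used) for _ in range(rng.randint(0, 3))],
            )
            return op
        if not tables:
            continue
        tname = rng.choice(tables)
        td = kb.get_table(tname)
        if op == "add_field":
            used = {f.name.lower() for f in td.fields}
            kb.add_field(tname, random_field(rng, used))
            return op
        if op == "insert_record":
            values = {
                fd.name: random_scalar(rng, fd.type)
                for fd in td.user_fields()
                if fd.type is not FieldType.REFERENCE and rng.random() < 0.7
            }
            kb.insert_record(tname, values)
            return op
        if op == "set_reference":
            ref_fields = [f for f in td.user_fields() if f.type is FieldType.REFERENCE]
            recs = [r.id for r in kb.iter_records(tname)]
            if not ref_fields or not recs:
                continue
            target_table = rng.choice(tables)
            targets = [r.id for r in kb.iter_records(target_table)]
            if not targets:
                continue
            kb.set_reference(
                tname,
                rng.choice(recs),
                rng.choice(ref_fields).name,
                target_table,
                rng.choice(targets),
            )
            return op
        if op == "delete_record":
            recs = [r.id for r in kb.iter_records(tname)]
            if not recs:
                continue
            kb.delete_record(tname, rng.choice(recs), policy="nullify")
            return op


def random_op_sequence(rng: random.Random, n_ops: int = 20) -> Knowledgebase:
    """Run a random interleaving of mutations from an empty knowledgebase."""
    kb = Knowledgebase()
    for _ in range(n_ops):
        random_operation(rng, kb)
    return kb


def plant_corruption(rng: random.Random, kb: Knowledgebase) -> Optional[tuple[str, str, int, str]]:
    """Corrupt one stored reference in place, bypassing the mutation API.

    Either renames the reference's target table to a never-created name
    (expected violation ``DANGLING_REF_TABLE``) or bumps its target id
    beyond the table's counter (``DANGLING_REF_RECORD``).  Returns
    ``(expected_code, table, record_id, field)``, or ``None`` if the
    knowledgebase holds no reference to corrupt.
    """
    sites = []
    for rec in kb.iter_records():
        for fname, val in rec.values.items():
            if isinstance(val, PolymorphicRef):
                sites.append((rec, fname, val))
    if not sites:
        return None
    rec, fname, val = rng.choice(sites)
    if rng.random() < 0.5:
        rec.values[fname] = PolymorphicRef("NeverCreatedTable", val.target_id)
        return ("DANGLING_REF_TABLE", rec.table, rec.id, fname)
    bogus = kb.counters[val.target_table.lower()] + rng.randint(1, 100)
    rec.values[fname] = PolymorphicRef(val.target_table, bogus)
    return ("DANGLING_REF_RECORD", rec.table, rec.id, fname)
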