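# Methods

## Data model

A knowledgebase is two stores plus bookkeeping:

* **Meta-database** — a map of runtime-defined `TableDef`s.  Each table
  owns an ordered list of `FieldDef`s; the first is always the
  system-created key `id` (INTEGER, assigned 1, 2, 3, … per table,
  never reused after deletion, tracked by a per-table counter).  Field
  types are `TEXT`, `INTEGER`, `DECIMAL`, `BOOLEAN`, `DATE` (ISO-8601
  text, `YYYY-MM-DD`), `ENUM`, and `REFERENCE`.  `REFERENCE` is the
  only type whose values are `(target_table, target_id)` pairs; the
  scalar set is this engine's own choice, sized to cover decision-flow
  content and a faithful SQL mapping.
* **Entity base** — per-table ordered record lists.  A record's
  `values` map always carries every non-system field (null allowed), so
  presence/absence never encodes meaning.
* **Counters and migration log** — the counter invariant
  `counter[t] ≥ max id in t` survives deletion, import and round trips.
  Every successful mutation appends one log entry
  (`CREATE_TABLE | ADD_FIELD | INSERT | SET_REF | CLEAR_REF | DELETE`);
  replaying the log from an empty knowledgebase reproduces the state
  exactly, which makes the log an audit trail rather than decoration.

Identifiers are case-insensitive for uniqueness, case-preserving for
display; this avoids silently distinct `Judgement`/`judgement` tables
when dumps move between SQL dialects with different folding rules.

## Reference discipline

References cannot be supplied at insert time: a `REFERENCE` value
enters the store only through `set_reference`, which checks the source
field's type, the target table's existence and *linkability* (the
single-unique-key rule below), and the target record's existence.
Consequently a knowledgebase mutated only through the public API can
never hold a dangling reference — a property the fuzz suite asserts
over randomized operation interleavings.  Clearing is a separate
idempotent operation; deletion is caller-policied (`restrict` refuses
while inbound references exist and names them; `nullify` blanks them
first and reports what it touched).  `restrict` is the default because
it is the safer behaviour during curation.

Record-level self-references are storable and surface in traversal as a
one-step cycle; decision flows may legitimately loop (re-test cycles),
so cycles are classified, never rejected.

The **single-unique-key rule** — only a table exposing exactly one
unique record key may be a reference target — is trivially true for
every table this engine creates, so it is enforced only where foreign
structure can enter: SQL import marks tables with extra unique columns
as non-linkable (refused as targets, flagged `TARGET_NOT_LINKABLE` by
validation), and a table without a single integer primary key is
rejected outright as an unrecognized schema shape.

## Validation

`validate_value` / `validate_kb` return violation values (code, table,
record id, field, message) instead of raising: curation needs the full
report.  Insert-time checking is deliberately type-only; declared
constraints (`required`, `unique`, `enum_values`, `pattern`,
`min_value`/`max_value`, `max_length`) are batch-enforced, so
half-entered knowledge (including a `required` reference still blank)
is representable between validations.  Null passes everything except
`required`; uniqueness treats nulls as non-conflicting (the standard
relational convention).  Report order is deterministic: tables in
creation order, records by id, fields in definition order, per-table
unique checks after per-value checks.  An `ENUM` field without an
`enum_values` constraint is allowed and behaves as unconstrained text.

## Evolution

`schema_fingerprint` renders one table's full definition as canonical
JSON (sorted keys, no whitespace); equal fingerprints iff structurally
identical definitions.  `extend_with_table` snapshots the
knowledgebase, applies create/insert/rewire through the ordinary
operations, re-asserts that every pre-existing fingerprint and every
non-rewired record value is unchanged, and rolls back wholesale on any
failure — atomicity is what makes interactive evolution safe.  The
independent cross-check `diff_after_extension` recomputes the same
claim from two full states without trusting the internal assertion.

## Serialization

The mind-map document is versioned YAML (`format_version: 1.0`) with
tables, records (references as explicit `{table, id}` locators) and
counters; the migration log is an audit artifact and is excluded, so
"serialization-equal" means equal *state*, not equal history.  The same
dump (`canonical_text`) is the byte-comparison currency used by the
closure-under-errors and rollback guarantees.  Strict loading rejects
documents with unresolvable references, naming the first offender;
permissive loading defers them to `validate_kb`.

SQL export emits one `CREATE TABLE` per table and one `INSERT` per
record, one statement per line, deterministic order (creation order,
then id).  Scalar mapping: TEXT/DATE/ENUM → `TEXT`, INTEGER →
`INTEGER`, DECIMAL → `REAL`, BOOLEAN → `BOOLEAN` (0/1 literals).  Each
reference field `f` becomes nullable `f_table` + `f_id` with a
paired-null CHECK; no native FOREIGN KEY is emitted for them, since a
key whose target table varies per row is exactly what the relational
model cannot express — integrity lives in validation.  Expressible
constraints become `NOT NULL`, `UNIQUE` and `CHECK` clauses.  What
executable SQL cannot carry (annotations, `pattern` constraints, exact
engine types) travels in `-- @meta` comment lines (plus a final
`-- @counters` line) that database engines ignore and the importer
prefers; dumps without them are parsed structurally, recovering types,
`NOT NULL`/`UNIQUE`, reference pairs by the `*_table`/`*_id` naming
convention, and linkability.  Known limitation: the line-oriented dump
refuses text values containing newlines (the YAML document handles them
fine).

## Traversal and rendering

`traverse_flow` follows one reference field, recording `(table, id)`
steps until the field is blank or absent (`BLANK_REF`), a reference
fails to resolve (`MISSING_TARGET`), or the next step is already on the
path (`CYCLE`, stopping *before* the repeat, so a self-loop is a
one-step cycle).  Visited-set bookkeeping bounds any walk by
record-count + 1 steps.  `render_dot` emits deterministic DOT (tables
sorted by name, records by id): one boxed node per record labelled
`Table#id`, clustered per table, one labelled edge per non-null
reference; a table filter drops hidden nodes together with edges
touching them.  Layout is delegated to DOT consumers.

## Worked example and extension scenario

The bundled fixture models the CPIC thiopurine CDS: `Judgement`
(criterion + `Next`), `DrugOrder` (terminal dosing suggestions) and
`CDSTestAlert` (alert + `Next`, so a pre-test alert can hand back into
the flow once results are on file).  Giving the alert table its own
`Next` is this package's modelling choice; it is what lets the root
walk visit all three action categories before terminating at a drug
order.  Record wording is a representative, non-normative paraphrase —
this is a modelling tool, not a clinical source, and nothing is fetched
from the guideline URLs cited in the code.  The ITPA extension adds one
`ITPATherapy` table with one record and rewires the
intermediate-metabolizer judgement's `Next` into the new branch; which
judgement moves is one representative reading of the scenario.

## Randomized testing

`polykb.fuzz` generates seeded random schemas (≤ 4 tables × ≤ 4 fields,
35 % of fields references), contents (≤ 6 records/table, 60–90 %
link-wiring probability) and operation interleavings, all driven by a
caller-owned `random.Random` for replayability.  These sizes keep
individual cases small enough that the acceptance checks run thousands
of them in seconds while still exercising self-links, cross-table
links, cycles and deletions.  `plant_corruption` bypasses the mutation
API to rename a reference's target table or bump its id past the
counter, yielding the expected violation code and location for
detection checks.  The generator emulates curation-shaped data
(identifier-like names, short text, no newlines, constraint-consistent
enum values); it does not emulate adversarial unicode, concurrent
editing, or very large entity bases, so passing fuzz runs demonstrate
engine invariants, not performance or robustness to hostile input.

Problem sizes used by `scripts/acceptance.py`: 1000 operation
sequences of 10 ops for reference integrity, 400 corruption plants, 200
knowledgebases per round-trip family, 150 knowledgebases of dense links
(~800 walks) for traversal — each family completes in about a second.
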