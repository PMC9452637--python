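# polykb

A prototyping engine for schema-flexible knowledgebases, built around the
**polymorphic foreign key**: a stored pair *(table identifier, record
identifier)* that lets a single field link to a record in *any* table.
A relational foreign key binds its target table at schema-design time; a
polymorphic reference defers that choice to each individual record, so a
high-level concept like "next step" can point at a judgement today and
at a therapy table that did not exist yesterday.

The intended users are curators of fast-evolving structured knowledge —
the motivating domain is precision-medicine knowledge such as
pharmacogenomic dosing guidance (CPIC-style clinical decision support
flows), where new knowledge categories arrive constantly and a frozen
relational schema becomes a liability.

## The model

A knowledgebase is a *meta-database* (runtime-defined tables with typed,
annotated, constrained fields) plus an *entity base* (records).  Every
table gets a system integer key `id` (1, 2, 3, …, never reused).  A
field of type `REFERENCE` holds either null or one pair
`(target_table, target_id)` resolving to exactly one record.  Schema
curation and content entry interleave freely: a reference is left blank
at insert time and wired afterwards (`set_reference`), so half-entered
knowledge is always representable and every stored link was validated
when it was made.

The payoff is the **no-touch evolution property**: integrating a new
knowledge category means *creating one new table and rewiring some
references* — the structure of every existing table, and every record
value outside the rewired fields, is provably unchanged.
`extend_with_table` applies such an extension atomically and verifies
the property itself via canonical schema fingerprints; a failed
extension rolls back completely.

Around the core sit batch integrity validation (machine-readable
violation codes: dangling references, constraint breaches, duplicate
unique values), a versioned YAML *mind-map document* (lossless round
trip; the node identity is `Table#id`), DOT graph rendering, and a
relational export in which each reference field `f` becomes the column
pair `f_table`/`f_id` with a paired-null CHECK — executable sqlite DDL
and DML that re-imports losslessly.

## Worked example

`polykb.build_cds_fixture()` models the CPIC thiopurine
(6-mercaptopurine, TPMT/NUDT15 genotypes) decision support flow.  The
flow distinguishes three categories of action — judgement, drug-order
suggestion, test-alert suggestion — and each category is one table, so
the entire CDS is stored in three tables chained through a single
`Next` reference field.

```bash
python examples/01_model_cds_flow.py
```

prints

```
tables: Judgement, DrugOrder, CDSTestAlert
records: 8
violations: 0
flow from Judgement#1: Judgement#1 -> CDSTestAlert#1 -> Judgement#2 -> DrugOrder#1
terminated by: BLANK_REF
```

i.e. the root judgement ("genotype results on file?") leads to a
pre-test alert, which hands back to a metabolizer judgement and ends at
a drug order; `DrugOrder` has no `Next` field, so the walk terminates
with a blank reference.  `examples/02_extend_with_itpa.py` then
integrates a hypothetical late-arriving ITPA genotype therapy:

```
added table ITPATherapy: 1 record(s), 1 rewire(s)
tables now: Judgement, DrugOrder, CDSTestAlert, ITPATherapy
pre-existing tables with unchanged structure: 3 of 3
record fields changed: [('Judgement', 3, 'Next')]
```

— the new category cost one table and one rewired link; nothing else
moved.  `examples/03_validate_integrity.py` and
`examples/04_export_roundtrip.py` demonstrate validation reports and
the SQL/mind-map round trips; `examples/rebuild_cds.sh` rebuilds the
whole fixture from the shell via the `polykb` CLI.

## Command line

The `polykb` command wraps the library for scripted sessions.  Each
subcommand loads a session file (a mind-map document), applies one
operation, and rewrites the file atomically — a failing command never
corrupts the session.

```bash
polykb --session cds.kb.yaml demo cds          # build the worked example
polykb --session cds.kb.yaml traverse Judgement 1
polykb --session cds.kb.yaml validate          # exit 1 if violations
polykb --session cds.kb.yaml render --out flow.dot
polykb --session cds.kb.yaml export-sql --out dump/
```

Exit codes: 0 success, 1 validation violations, 2 errors (engine errors
carry machine-readable codes such as `unknown-target-record`).

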