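"""Relational DDL+DML export, executability, and re-import."""

import sqlite3

import pytest

from polykb import (
    canonical_text,
    errors,
    execute_dump,
    export_ddl,
    export_dml,
    export_sql,
    import_dump,
)
from polykb.model import (
    FieldConstraint,
    FieldDef,
    FieldType,
    Knowledgebase,
    PolymorphicRef,
)
from polykb.validation import ViolationCode


class TestExportDDL:
    def test_reference_field_becomes_paired_columns(self, small_kb):
        create = [s for s in export_ddl(small_kb) if s.startswith("CREATE")][0]
        assert '"Next_table" TEXT' in create
        assert '"Next_id" INTEGER' in create
        assert 'CHECK (("Next_table" IS NULL) = ("Next_id" IS NULL))' in create

    def test_fixture_exports_exactly_three_create_tables(self, cds_kb):
        creates = [s for s in export_ddl(cds_kb) if s.upper().startswith("CREATE TABLE")]
        assert len(creates) == 3

    def test_deterministic(self, cds_kb):
        assert export_ddl(cds_kb) == export_ddl(cds_kb)
        assert export_dml(cds_kb) == export_dml(cds_kb)

    def test_system_key_is_integer_primary_key(self, small_kb):
        create = [s for s in export_ddl(small_kb) if s.startswith("CREATE")][0]
        assert '"id" INTEGER PRIMARY KEY' in create

    def test_unclean_kb_refused_without_force(self, small_kb):
        small_kb.get_record("Step", 1).values["Next"] = PolymorphicRef("Ghost", 1)
        with pytest.raises(errors.UncleanKB):
            export_ddl(small_kb)
        with pytest.raises(errors.UncleanKB):
            export_dml(small_kb)
        assert export_ddl(small_kb, force=True)  # force overrides

    def test_declared_constraints_appear_in_sql(self):
        kb = Knowledgebase()
        kb.create_table(
            "T",
            [
                FieldDef("a", FieldType.TEXT, constraints=[FieldConstraint("required"),
                                                           FieldConstraint("unique")]),
                FieldDef("lvl", FieldType.ENUM,
                         constraints=[FieldConstraint("enum_values", ["low", "high"])]),
                FieldDef("dose", FieldType.DECIMAL,
                         constraints=[FieldConstraint("min_value", 0)]),
            ],
        )
        create = [s for s in export_ddl(kb) if s.startswith("CREATE")][0]
        assert "NOT NULL" in create and "UNIQUE" in create
        assert "IN ('low', 'high')" in create
        assert '"dose" >= 0' in create


class TestExportDML:
    def test_empty_table_emits_no_inserts(self):
        kb = Knowledgebase()
        kb.create_table("T", [])
        assert export_dml(kb) == []

    def test_blank_ref_exported_as_paired_nulls(self, small_kb):
        small_kb.clear_reference("Step", 1, "Next")
        stmt = [s for s in export_dml(small_kb) if '"Step"' in s][0]
        assert "NULL, NULL" in stmt

    def test_linked_fixture_record_carries_target_pair(self, cds_kb):
        ref = cds_kb.get_record("Judgement", 2).values["Next"]
        assert ref == PolymorphicRef("DrugOrder", 1)
        stmt = [s for s in export_dml(cds_kb) if '"Judgement"' in s][1]
        assert "'DrugOrder', 1" in stmt

    def test_newline_in_text_is_rejected(self):
        kb = Knowledgebase()
        kb.create_table("T", [FieldDef("t", FieldType.TEXT)])
        kb.insert_record("T", {"t": "two\nlines"})
        with pytest.raises(errors.KBError):
            export_dml(kb)


class TestExecutability:
    def test_fixture_dump_runs_on_sqlite(self, cds_kb):
        conn = execute_dump(export_sql(cds_kb))
        n = conn.execute('SELECT COUNT(*) FROM "Judgement"').fetchone()[0]
        assert n == len(list(cds_kb.iter_records("Judgement")))
        pair = conn.execute(
            'SELECT "Next_table", "Next_id" FROM "Judgement" WHERE id=1'
        ).fetchone()
        assert pair == ("CDSTestAlert", 1)


class TestImportDump:
    def test_round_trip_of_fixture(self, cds_kb):
        kb2, violations = import_dump(export_sql(cds_kb))
        assert violations == []
        assert canonical_text(kb2) == canonical_text(cds_kb)

    def test_empty_dump(self):
        kb, violations = import_dump([])
        assert kb.table_names() == [] and violations == []

    def test_counters_restored_from_dump(self):
        kb = Knowledgebase()
        kb.create_table("T", [])
        kb.insert_record("T")
        kb.insert_record("T")
        kb.delete_record("T", 2)
        kb2, _ = import_dump(export_sql(kb))
        assert kb2.insert_record("T").id == 3

    def test_planted_ghost_ref_surfaces_as_violation(self, small_kb):
        stmts = [
            s.replace("'Outcome', 1", "'Ghost', 1") if s.startswith("INSERT") else s
            for s in export_sql(small_kb)
        ]
        kb2, violations = import_dump(stmts)
        assert [v.code for v in violations] == [ViolationCode.DANGLING_REF_TABLE]

    def test_foreign_dump_without_meta_parses_structurally(self):
        stmts = [
            'CREATE TABLE "Step" ("id" INTEGER PRIMARY KEY, "title" TEXT NOT NULL, '
            '"Next_table" TEXT, "Next_id" INTEGER);',
            'CREATE TABLE "Outcome" ("id" INTEGER PRIMARY KEY, "label" TEXT);',
            'INSERT INTO "Step" ("id", "title", "Next_table", "Next_id") '
            "VALUES (1, 'check', 'Outcome', 2);",
            'INSERT INTO "Outcome" ("id", "label") VALUES (2, \'done\');',
        ]
        kb, violations = import_dump(stmts)
        assert violations == []
        td = kb.get_table("Step")
        assert [f.name for f in td.fields] == ["id", "title", "Next"]
        assert td.get_field("Next").type is FieldType.REFERENCE
        assert [c.kind for c in td.get_field("title").constraints] == ["required"]
        assert kb.get_record("Step", 1).values["Next"] == PolymorphicRef("Outcome", 2)

    def test_extra_unique_key_marks_table_not_linkable(self):
        stmts = [
            'CREATE TABLE "Multi" ("id" INTEGER PRIMARY KEY, "code" TEXT UNIQUE);',
            'CREATE TABLE "Step" ("id" INTEGER PRIMARY KEY, '
            '"Next_table" TEXT, "Next_id" INTEGER);',
            'INSERT INTO "Multi" ("id", "code") VALUES (1, \'x\');',
            'INSERT INTO "Step" ("id", "Next_table", "Next_id") '
            "VALUES (1, 'Multi', 1);",
        ]
        kb, violations = import_dump(stmts)
        assert not kb.get_table("Multi").linkable
        assert [v.code for v in violations] == [ViolationCode.TARGET_NOT_LINKABLE]
        with pytest.raises(errors.TargetTableNotLinkable):
            kb.set_reference("Step", 1, "Next", "Multi", 1)

    @pytest.mark.parametrize(
        "stmt",
        [
            'CREATE TABLE "NoPK" ("a" TEXT, "b" TEXT);',
            'CREATE TABLE "CompositePK" ("a" INTEGER, "b" INTEGER, PRIMARY KEY (a, b));',
            'CREATE TABLE "TextPK" ("id" TEXT PRIMARY KEY);',
            "DROP TABLE x;",
        ],
    )
    def test_unrecognized_shapes_rejected(self, stmt):
        with pytest.raises(errors.UnrecognizedSchemaShape):
            import_dump([stmt])

    def test_import_from_live_connection(self, cds_kb):
        conn = execute_dump(export_sql(cds_kb))
        kb2, violations = import_dump(conn)
        assert violations == []
        assert kb2.table_names() == cds_kb.table_names()
        assert kb2.record_count() == cds_kb.record_count()
        assert kb2.get_record("Judgement", 1).values["Next"] == PolymorphicRef(
            "CDSTestAlert", 1
        )
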