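"""Runtime schema curation, content entry, and reference linking."""

import pytest

from polykb import canonical_text, errors
from polykb.model import (
    FieldConstraint,
    FieldDef,
    FieldType,
    Knowledgebase,
    PolymorphicRef,
)


def make_kb():
    return Knowledgebase()


class TestCreateTable:
    def test_system_key_prepended(self):
        kb = make_kb()
        td = kb.create_table(
            "Judgement",
            [FieldDef("criterion", FieldType.TEXT), FieldDef("Next", FieldType.REFERENCE)],
        )
        assert [f.name for f in td.fields] == ["id", "criterion", "Next"]
        assert td.fields[0].system_key and td.fields[0].type is FieldType.INTEGER

    def test_zero_user_fields_gives_only_system_key(self):
        td = make_kb().create_table("Empty", [])
        assert [f.name for f in td.fields] == ["id"]

    def test_two_tables_listed_in_creation_order(self):
        kb = make_kb()
        kb.create_table("B_second_created_first", [])
        kb.create_table("A_first_alphabetically", [])
        assert kb.table_names() == ["B_second_created_first", "A_first_alphabetically"]

    @pytest.mark.parametrize(
        "name, exc",
        [
            ("Judgement", errors.DuplicateTableName),
            ("JUDGEMENT", errors.DuplicateTableName),  # case-insensitive uniqueness
            ("9bad", errors.InvalidIdentifier),
            ("bad name", errors.InvalidIdentifier),
            ("", errors.InvalidIdentifier),
        ],
    )
    def test_bad_table_names(self, name, exc):
        kb = make_kb()
        kb.create_table("Judgement", [])
        with pytest.raises(exc):
            kb.create_table(name, [])

    def test_user_field_named_id_is_reserved(self):
        with pytest.raises(errors.ReservedFieldName):
            make_kb().create_table("T", [FieldDef("ID", FieldType.TEXT)])

    def test_duplicate_field_names_case_insensitive(self):
        with pytest.raises(errors.DuplicateFieldName):
            make_kb().create_table(
                "T", [FieldDef("x", FieldType.TEXT), FieldDef("X", FieldType.INTEGER)]
            )

    def test_display_case_preserved(self):
        kb = make_kb()
        kb.create_table("MixedCase", [])
        assert kb.get_table("mixedcase").name == "MixedCase"

    @pytest.mark.parametrize(
        "field",
        [
            FieldDef("x", FieldType.TEXT, constraints=[FieldConstraint("min_value", 0)]),
            FieldDef("r", FieldType.REFERENCE, constraints=[FieldConstraint("unique")]),
            FieldDef("e", FieldType.INTEGER, constraints=[FieldConstraint("enum_values", ["a"])]),
            FieldDef("p", FieldType.TEXT, constraints=[FieldConstraint("pattern", "[")]),
        ],
    )
    def test_inapplicable_constraints_rejected(self, field):
        with pytest.raises(errors.InvalidConstraint):
            make_kb().create_table("T", [field])


class TestInsertRecord:
    def test_first_id_is_one_then_monotonic(self):
        kb = make_kb()
        kb.create_table("T", [FieldDef("v", FieldType.INTEGER)])
        assert kb.insert_record("T", {"v": 1}).id == 1
        assert kb.insert_record("T").id == 2

    def test_ids_never_reused_after_deletion(self):
        kb = make_kb()
        kb.create_table("T", [])
        for _ in range(3):
            kb.insert_record("T")
        kb.delete_record("T", 2)
        assert kb.insert_record("T").id == 4
        assert sorted(r.id for r in kb.iter_records("T")) == [1, 3, 4]

    def test_omitted_fields_stored_null(self):
        kb = make_kb()
        kb.create_table(
            "T", [FieldDef("a", FieldType.TEXT), FieldDef("Next", FieldType.REFERENCE)]
        )
        rec = kb.insert_record("T", {"a": "x"})
        assert rec.values == {"a": "x", "Next": None}

    def test_reference_value_rejected_at_insert(self):
        kb = make_kb()
        kb.create_table("T", [FieldDef("Next", FieldType.REFERENCE)])
        kb.insert_record("T")
        with pytest.raises(errors.ReferenceAtInsert):
            kb.insert_record("T", {"Next": PolymorphicRef("T", 1)})

    def test_null_reference_allowed_at_insert(self):
        kb = make_kb()
        kb.create_table("T", [FieldDef("Next", FieldType.REFERENCE)])
        assert kb.insert_record("T", {"Next": None}).values["Next"] is None

    @pytest.mark.parametrize(
        "ftype, good, bad",
        [
            (FieldType.TEXT, "s", 1),
            (FieldType.INTEGER, 3, "abc"),
            (FieldType.INTEGER, -1, True),  # bools are not integers here
            (FieldType.DECIMAL, 2.5, "2.5"),
            (FieldType.BOOLEAN, True, 1),
            (FieldType.DATE, "2022-08-25", "2022-13-01"),
            (FieldType.ENUM, "low", 5),
        ],
    )
    def test_scalar_type_checking(self, ftype, good, bad):
        kb = make_kb()
        kb.create_table("T", [FieldDef("v", ftype)])
        assert kb.insert_record("T", {"v": good}).values["v"] == good
        with pytest.raises(errors.TypeMismatch):
            kb.insert_record("T", {"v": bad})

    def test_unknown_table_and_field(self):
        kb = make_kb()
        kb.create_table("T", [])
        with pytest.raises(errors.UnknownTable):
            kb.insert_record("Nope")
        with pytest.raises(errors.UnknownField):
            kb.insert_record("T", {"ghost": 1})


class TestAddField:
    def test_existing_records_backfilled_with_null(self):
        kb = make_kb()
        kb.create_table("T", [])
        kb.insert_record("T")
        kb.insert_record("T")
        kb.add_field("T", FieldDef("note", FieldType.TEXT))
        assert all(r.values["note"] is None for r in kb.iter_records("T"))

    def test_reserved_and_duplicate_names(self):
        kb = make_kb()
        kb.create_table("T", [FieldDef("x", FieldType.TEXT)])
        with pytest.raises(errors.ReservedFieldName):
            kb.add_field("T", FieldDef("id", FieldType.TEXT))
        with pytest.raises(errors.DuplicateFieldName):
            kb.add_field("T", FieldDef("X", FieldType.INTEGER))

    def test_required_field_added_late_flags_existing_records(self):
        from polykb import validate_kb
        from polykb.validation import ViolationCode

        kb = make_kb()
        kb.create_table("T", [])
        n_before = 3
        for _ in range(n_before):
            kb.insert_record("T")
        kb.add_field(
            "T", FieldDef("must", FieldType.TEXT, constraints=[FieldConstraint("required")])
        )
        hits = [v for v in validate_kb(kb) if v.code is ViolationCode.REQUIRED_NULL]
        assert len(hits) == n_before


class TestReferences:
    def test_link_resolves_to_target(self, small_kb):
        ref = small_kb.get_record("Step", 1).values["Next"]
        assert ref == PolymorphicRef("Outcome", 1)
        assert small_kb.resolve_reference(ref).values["label"] == "done"

    def test_self_table_link_allowed(self):
        kb = make_kb()
        kb.create_table("J", [FieldDef("Next", FieldType.REFERENCE)])
        kb.insert_record("J")
        kb.insert_record("J")
        kb.set_reference("J", 1, "Next", "J", 2)
        assert kb.get_record("J", 1).values["Next"] == PolymorphicRef("J", 2)

    def test_self_record_link_allowed(self):
        kb = make_kb()
        kb.create_table("J", [FieldDef("Next", FieldType.REFERENCE)])
        kb.insert_record("J")
        kb.set_reference("J", 1, "Next", "J", 1)
        assert kb.get_record("J", 1).values["Next"] == PolymorphicRef("J", 1)

    def test_failed_link_is_a_noop(self, small_kb, snapshot):
        before = snapshot(small_kb)
        with pytest.raises(errors.UnknownTargetRecord):
            small_kb.set_reference("Step", 1, "Next", "Outcome", 99)
        assert snapshot(small_kb) == before

    def test_relink_replaces_previous_target(self, small_kb):
        small_kb.insert_record("Outcome", {"label": "later"})
        small_kb.set_reference("Step", 1, "Next", "Outcome", 2)
        assert small_kb.get_record("Step", 1).values["Next"] == PolymorphicRef("Outcome", 2)

    def test_set_clear_set_last_write_wins(self, small_kb):
        small_kb.insert_record("Outcome", {"label": "later"})
        small_kb.clear_reference("Step", 1, "Next")
        assert small_kb.get_record("Step", 1).values["Next"] is None
        small_kb.clear_reference("Step", 1, "Next")  # idempotent
        small_kb.set_reference("Step", 1, "Next", "Outcome", 2)
        assert small_kb.get_record("Step", 1).values["Next"] == PolymorphicRef("Outcome", 2)

    def test_not_a_reference_field(self, small_kb):
        with pytest.raises(errors.NotAReferenceField):
            small_kb.set_reference("Step", 1, "title", "Outcome", 1)
        with pytest.raises(errors.NotAReferenceField):
            small_kb.clear_reference("Step", 1, "title")

    def test_link_into_non_linkable_table_rejected(self, small_kb):
        small_kb.get_table("Outcome").linkable = False  # as after a foreign import
        with pytest.raises(errors.TargetTableNotLinkable):
            small_kb.set_reference("Step", 1, "Next", "Outcome", 1)

    def test_resolution_outcomes_are_distinct(self, small_kb):
        with pytest.raises(errors.UnknownTargetTable):
            small_kb.resolve_reference(PolymorphicRef("Ghost", 1))
        with pytest.raises(errors.UnknownTargetRecord):
            small_kb.resolve_reference(PolymorphicRef("Outcome", 9))

    def test_resolve_after_delete_reports_missing_record(self, small_kb):
        small_kb.clear_reference("Step", 1, "Next")
        small_kb.delete_record("Outcome", 1)
        with pytest.raises(errors.UnknownTargetRecord):
            small_kb.resolve_reference(PolymorphicRef("Outcome", 1))


class TestDeleteRecord:
    def test_restrict_blocks_and_names_referrers(self, small_kb):
        with pytest.raises(errors.RestrictedByInboundRefs) as ei:
            small_kb.delete_record("Outcome", 1)
        assert ei.value.blockers == [("Step", 1, "Next")]
        # blocked delete left everything intact
        assert small_kb.get_record("Outcome", 1) is not None

    def test_restrict_on_unreferenced_record(self, small_kb):
        assert small_kb.delete_record("Step", 1, policy="restrict") == []

    def test_nullify_blanks_inbound_refs(self, small_kb):
        from polykb import validate_kb

        affected = small_kb.delete_record("Outcome", 1, policy="nullify")
        assert affected == [("Step", 1, "Next")]
        assert small_kb.get_record("Step", 1).values["Next"] is None
        assert validate_kb(small_kb) == []


@pytest.mark.parametrize(
    "op",
    [
        lambda kb: kb.create_table("Step", []),  # duplicate table
        lambda kb: kb.create_table("bad name", []),
        lambda kb: kb.add_field("Step", FieldDef("title", FieldType.TEXT)),
        lambda kb: kb.add_field("Ghost", FieldDef("x", FieldType.TEXT)),
        lambda kb: kb.insert_record("Step", {"title": 5}),
        lambda kb: kb.insert_record("Step", {"ghost": 1}),
        lambda kb: kb.set_reference("Step", 9, "Next", "Outcome", 1),
        lambda kb: kb.set_reference("Step", 1, "Next", "Ghost", 1),
        lambda kb: kb.set_reference("Step", 1, "Next", "Outcome", 9),
        lambda kb: kb.set_reference("Step", 1, "title", "Outcome", 1),
        lambda kb: kb.clear_reference("Step", 9, "Next"),
        lambda kb: kb.delete_record("Step", 9),
        lambda kb: kb.delete_record("Outcome", 1),  # restricted
    ],
)
def test_closure_under_errors(small_kb, snapshot, op):
    """A raising operation leaves the knowledgebase byte-identical."""
    before = snapshot(small_kb)
    log_len = len(small_kb.migration_log)
    with pytest.raises(errors.KBError):
        op(small_kb)
    assert snapshot(small_kb) == before
    assert len(small_kb.migration_log) == log_len
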