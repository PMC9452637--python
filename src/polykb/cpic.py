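"""Worked example: a CPIC thiopurine clinical decision support flow.

The CPIC guideline for thiopurines (6-mercaptopurine dosing by TPMT and
NUDT15 genotype) is a point-of-care decision flow in which a patient in
a given diagnostic state is directed to a next step.  Three categories
of action occur in the flow — a judgement on a criterion, a drug-order
suggestion, and a test-alert suggestion — and the whole CDS is modelled
here as three tables, one per category, chained through a single
polymorphic reference field ``Next``:

* ``Judgement`` — a criterion on the patient's state, plus ``Next``;
* ``DrugOrder`` — a dosing suggestion (terminal: no ``Next`` field);
* ``CDSTestAlert`` — an alert to the ordering clinician, plus ``Next``
  so that a pre-test alert can hand back into the flow once the
  genotype result is on file.

Record wording is a representative, non-normative paraphrase of the
published flow: this package is a modelling tool, not a clinical
source.  The guideline documents live at https://cpicpgx.org/ and are
cited here for orientation only; nothing is fetched.

A hypothetical later discovery — an ITPA genotype result with its own
therapy specification — is provided as a declarative extension
(:func:`build_itpa_extension`): one new table plus one reference rewire,
leaving every pre-existing table untouched.
"""

from __future__ import annotations

from .evolution import ExtensionSpec, Rewire
from .model import FieldConstraint, FieldDef, FieldType, Knowledgebase

#: the three action categories the decision flow distinguishes
ACTION_CATEGORIES = ("judgement", "drug order suggestion", "test alert suggestion")

#: table modelling each category
CATEGORY_TABLES = {
    "judgement": "Judgement",
    "drug order suggestion": "DrugOrder",
    "test alert suggestion": "CDSTestAlert",
}


def build_cds_fixture() -> Knowledgebase:
    """Build the thiopurine CDS knowledgebase: 3 tables, linked flow.

    The root of the flow is ``Judgement#1``.  Following ``Next`` from it
    visits a test alert (order genotyping) and, once results are on
    file, a metabolizer judgement ending in a drug order — so the walk
    touches all three action categories before terminating.
    """
    kb = Knowledgebase()
    kb.create_table(
        "Judgement",
        [
            FieldDef(
                "criterion",
                FieldType.TEXT,
                annotation="Decision criterion on the patient's diagnostic state",
                constraints=[FieldConstraint("required")],
            ),
            FieldDef(
                "Next",
                FieldType.REFERENCE,
                annotation="Next step in the decision flow (any action table)",
            ),
        ],
    )
    kb.create_table(
        "DrugOrder",
        [
            FieldDef(
                "description",
                FieldType.TEXT,
                annotation="Dosing suggestion presented to the ordering clinician",
                constraints=[FieldConstraint("required")],
            ),
        ],
    )
    kb.create_table(
        "CDSTestAlert",
        [
            FieldDef(
                "alert",
                FieldType.TEXT,
                annotation="Interruptive alert text shown at order entry",
                constraints=[FieldConstraint("required")],
            ),
            FieldDef(
                "Next",
                FieldType.REFERENCE,
                annotation="Step the flow resumes at after the alert is actioned",
            ),
        ],
    )

    # judgement chain (references wired after all targets exist, mirroring
    # the blank-then-link entry workflow)
    kb.insert_record(
        "Judgement",
        {"criterion": "TPMT and NUDT15 genotype results on file?"},
    )
    kb.insert_record(
        "Judgement",
        {"criterion": "Normal metabolizer phenotype for both TPMT and NUDT15?"},
    )
    kb.insert_record(
        "Judgement",
        {"criterion": "Intermediate metabolizer for TPMT or NUDT15?"},
    )
    kb.insert_record(
        "Judgement",
        {"criterion": "Poor metabolizer for TPMT or NUDT15?"},
    )
    kb.insert_record(
        "DrugOrder",
        {"description": "Start 6-mercaptopurine at the standard protocol dose."},
    )
    kb.insert_record(
        "DrugOrder",
        {
            "description": (
                "Start 6-mercaptopurine at a reduced dose (30-80% of the "
                "standard dose) and adjust by tolerance."
            )
        },
    )
    kb.insert_record(
        "CDSTestAlert",
        {
            "alert": (
                "Pre-test alert: order TPMT and NUDT15 genotyping before "
                "starting thiopurine therapy."
            )
        },
    )
    kb.insert_record(
        "CDSTestAlert",
        {
            "alert": (
                "Post-test alert: poor metabolizer detected; drastically "
                "reduce the dose or consider an alternative agent."
            )
        },
    )

    kb.set_reference("Judgement", 1, "Next", "CDSTestAlert", 1)  # no result yet
    kb.set_reference("CDSTestAlert", 1, "Next", "Judgement", 2)  # re-check
    kb.set_reference("Judgement", 2, "Next", "DrugOrder", 1)  # normal dose
    kb.set_reference("Judgement", 3, "Next", "DrugOrder", 2)  # reduced dose
    kb.set_reference("Judgement", 4, "Next", "CDSTestAlert", 2)  # PM alert
    return kb


ROOT_JUDGEMENT = ("Judgement", 1)


def build_itpa_extension() -> ExtensionSpec:
    """Declarative extension for the hypothetical ITPA discovery.

    Adds one new table ``ITPATherapy`` holding the new therapy
    specification and rewires the intermediate-metabolizer judgement's
    ``Next`` into the new branch — one representative reading of the
    depicted change; no pre-existing table is touched.
    """
    return ExtensionSpec(
        name="ITPATherapy",
        fields=[
            FieldDef(
                "description",
                FieldType.TEXT,
                annotation="Therapy specification for the ITPA genotype result",
                constraints=[FieldConstraint("required")],
            ),
        ],
        records=[
            {
                "description": (
                    "ITPA-deficient genotype on file: use the ITPA-adjusted "
                    "thiopurine therapy specification."
                )
            }
        ],
        rewires=[
            Rewire(
                table="Judgement",
                record_id=3,
                field="Next",
                target_table="ITPATherapy",
                target_id=1,
            )
        ],
    )
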