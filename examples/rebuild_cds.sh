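#!/usr/bin/env bash
# Rebuild the thiopurine CDS worked example purely through CLI commands.
# Usage:  SESSION=cds.kb.yaml bash examples/rebuild_cds.sh
# The resulting session file is serialization-equal to the knowledgebase
# returned by polykb.build_cds_fixture().
set -euo pipefail
SESSION="${SESSION:-cds.kb.yaml}"

polykb --session "$SESSION" init

# schema: one table per action category of the decision flow
polykb --session "$SESSION" table add Judgement -f "criterion:TEXT:Decision criterion on the patient's diagnostic state" -f "Next:REFERENCE:Next step in the decision flow (any action table)" -c "criterion:required"
polykb --session "$SESSION" table add DrugOrder -f "description:TEXT:Dosing suggestion presented to the ordering clinician" -c "description:required"
polykb --session "$SESSION" table add CDSTestAlert -f "alert:TEXT:Interruptive alert text shown at order entry" -f "Next:REFERENCE:Step the flow resumes at after the alert is actioned" -c "alert:required"

# content: reference fields stay blank until every target exists
polykb --session "$SESSION" record add Judgement --set "criterion=TPMT and NUDT15 genotype results on file?"
polykb --session "$SESSION" record add Judgement --set "criterion=Normal metabolizer phenotype for both TPMT and NUDT15?"
polykb --session "$SESSION" record add Judgement --set "criterion=Intermediate metabolizer for TPMT or NUDT15?"
polykb --session "$SESSION" record add Judgement --set "criterion=Poor metabolizer for TPMT or NUDT15?"
polykb --session "$SESSION" record add DrugOrder --set "description=Start 6-mercaptopurine at the standard protocol dose."
polykb --session "$SESSION" record add DrugOrder --set "description=Start 6-mercaptopurine at a reduced dose (30-80% of the standard dose) and adjust by tolerance."
polykb --session "$SESSION" record add CDSTestAlert --set "alert=Pre-test alert: order TPMT and NUDT15 genotyping before starting thiopurine therapy."
polykb --session "$SESSION" record add CDSTestAlert --set "alert=Post-test alert: poor metabolizer detected; drastically reduce the dose or consider an alternative agent."

# wire the flow
polykb --session "$SESSION" link Judgement 1 Next CDSTestAlert 1
polykb --session "$SESSION" link CDSTestAlert 1 Next Judgement 2
polykb --session "$SESSION" link Judgement 2 Next DrugOrder 1
polykb --session "$SESSION" link Judgement 3 Next DrugOrder 2
polykb --session "$SESSION" link Judgement 4 Next CDSTestAlert 2

polykb --session "$SESSION" validate
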