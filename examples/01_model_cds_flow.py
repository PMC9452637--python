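"""Model a pharmacogenetic decision flow with polymorphic references.

Builds the thiopurine (6-mercaptopurine, TPMT/NUDT15) clinical decision
support example — one table per action category, all chained through a
single reference field ``Next`` — and walks the flow from its root.
"""

from polykb import build_cds_fixture, traverse_flow, validate_kb

kb = build_cds_fixture()

print("tables:", ", ".join(kb.table_names()))
print("records:", kb.record_count())
print("violations:", len(validate_kb(kb)))

path = traverse_flow(kb, "Judgement", 1)
print("flow from Judgement#1:", " -> ".join(f"{t}#{i}" for t, i in path.steps))
print("terminated by:", path.terminated_by)

# What the numbers mean: the whole decision support flow lives in 3
# tables (one per action category); the walk from the root judgement
# crosses a test alert and a follow-up judgement before ending at a
# drug order, whose table has no 'Next' field (BLANK_REF).
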