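"""Add a new knowledge category without touching existing tables.

A new genotype test result (ITPA) and its therapy arrive after the
knowledgebase was built.  The extension is one new table plus one
reference rewire; every pre-existing table's structure and every
untouched record value is provably unchanged.
"""

from polykb import (
    build_cds_fixture,
    build_itpa_extension,
    diff_after_extension,
    extend_with_table,
    schema_fingerprint,
)

kb = build_cds_fixture()
pre = kb.copy()
fingerprints = {t: schema_fingerprint(kb, t) for t in kb.table_names()}

report = extend_with_table(kb, build_itpa_extension())
print(f"added table {report.table}: {report.records_inserted} record(s), "
      f"{report.rewires_applied} rewire(s)")
print("tables now:", ", ".join(kb.table_names()))

unchanged = [t for t in fingerprints if schema_fingerprint(kb, t) == fingerprints[t]]
print("pre-existing tables with unchanged structure:", len(unchanged), "of", len(fingerprints))

diff = diff_after_extension(pre, kb)
print("record fields changed:", diff["fields_changed"])

# What the numbers mean: integrating the new category cost one CREATE
# and one rewired link; 3 of 3 original tables keep their exact
# structure, and the only changed value is the rewired Judgement#3.Next.
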