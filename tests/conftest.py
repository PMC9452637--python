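import pytest

from polykb import build_cds_fixture, build_itpa_extension, canonical_text
from polykb.model import FieldDef, FieldType, Knowledgebase


@pytest.fixture
def cds_kb():
    return build_cds_fixture()


@pytest.fixture
def itpa_spec():
    return build_itpa_extension()


@pytest.fixture
def small_kb():
    """Two tables, one wired reference: the minimal linked knowledgebase."""
    kb = Knowledgebase()
    kb.create_table(
        "Step",
        [FieldDef("title", FieldType.TEXT), FieldDef("Next", FieldType.REFERENCE)],
    )
    kb.create_table("Outcome", [FieldDef("label", FieldType.TEXT)])
    kb.insert_record("Step", {"title": "check"})
    kb.insert_record("Outcome", {"label": "done"})
    kb.set_reference("Step", 1, "Next", "Outcome", 1)
    return kb


@pytest.fixture
def snapshot():
    """Byte-level state snapshot helper for closure-under-errors checks."""
    return canonical_text
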