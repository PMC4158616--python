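import pytest

from glyphscape.data_model import MISSING, CaseRecord, Dataset, VariableMeta
from glyphscape.glyph_spec import GlyphMapping, cubic_glyph_spec


@pytest.fixture(scope="session")
def spec():
    return cubic_glyph_spec()


def make_dataset(rows, metas):
    """Build a Dataset from a list of dicts plus VariableMeta list."""
    return Dataset(records=[CaseRecord(dict(r)) for r in rows], variables=metas)


@pytest.fixture
def six_cases():
    """Printed six-record fixture used by the filter oracle tests."""
    rows = [
        {"age": 45, "sex": "F", "t_stage": "T1"},
        {"age": 52, "sex": "M", "t_stage": "T2"},
        {"age": 55, "sex": "F", "t_stage": MISSING},
        {"age": 60, "sex": "F", "t_stage": "T4"},
        {"age": MISSING, "sex": "M", "t_stage": "T3"},
        {"age": 58, "sex": "F", "t_stage": "T2"},
    ]
    metas = [
        VariableMeta("age", "continuous", (45, 60), 5, missing_count=1),
        VariableMeta("sex", "nominal", ["M", "F"], 2),
        VariableMeta(
            "t_stage", "ordinal", ["T1", "T2", "T3", "T4"], 4, missing_count=1
        ),
    ]
    return make_dataset(rows, metas)


@pytest.fixture
def registry_metas():
    """Metadata for the hand-built pyramid/render fixtures."""
    return {
        "age": VariableMeta("age", "continuous", (0, 100), 80),
        "sex": VariableMeta("sex", "nominal", ["M", "F"], 2),
        "t_stage": VariableMeta("t_stage", "ordinal", ["T1", "T2", "T3", "T4"], 4),
        "deceased": VariableMeta("deceased", "nominal", ["no", "yes"], 2),
    }


@pytest.fixture
def basic_mapping():
    return GlyphMapping(assignments={1: "t_stage", 2: "age", 3: "deceased"})
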