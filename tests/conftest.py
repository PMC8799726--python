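import pytest

from splicequant import (
    AmpliconDesign,
    ExonSegment,
    SegmentRole,
    SpliceForm,
    build_diagnostics,
    default_design,
)


def make_design(cl, m, l, cr, barcodes, control="", quatromer_length=4):
    segments = {
        SegmentRole.CONST_LEFT: ExonSegment("CL", cl, SegmentRole.CONST_LEFT),
        SegmentRole.ALT_M: ExonSegment("M", m, SegmentRole.ALT_M),
        SegmentRole.ALT_L: ExonSegment("L", l, SegmentRole.ALT_L),
        SegmentRole.CONST_RIGHT: ExonSegment("CR", cr, SegmentRole.CONST_RIGHT),
    }
    return AmpliconDesign(
        segments=segments,
        barcodes=barcodes,
        control_sequence=control,
        quatromer_length=quatromer_length,
    )


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def diagnostics(design):
    return build_diagnostics(design)


@pytest.fixture
def toy_design():
    return make_design("AAAA", "CC", "G", "TTTT", ["AACCGGTT", "TTGGCCAA"])


@pytest.fixture(scope="session")
def standard_proportions():
    return {
        SpliceForm.NULL: 0.60,
        SpliceForm.M_ONLY: 0.30,
        SpliceForm.BOTH: 0.08,
        SpliceForm.L_ONLY: 0.02,
    }
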