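import pytest

from mirseedscan.io_formats import SequenceRecord
from mirseedscan.precursor_fold import BuiltinFoldEngine, get_engine
from mirseedscan.synthetic_data import PATHWAY_MATURES

# Published hairpin table for the five isoflavone-pathway miRNAs:
# id -> (mature, mature_len, precursor_len, GC%, MFE,
#        printed MFEI, printed AMFE, printed AU%)
HAIRPIN_TABLE = {
    "Gma_miRNA12": ("AGACAGUUAUUUUGGGACGGA", 21, 121, 41.32231, -44.0,
                    -0.88, -36.36, 58.67769),
    "Gma_miRNA24": ("UCUUGAAGUCUCGCUUGCAG", 20, 120, 49.16667, -36.3,
                    -0.61, -30.25, 50.83333),
    "Gma_miRNA26": ("UAAUUGUCGCAGUUUUGAACU", 21, 121, 31.40496, -36.1,
                    -0.95, -29.83, 68.59504),
    "Gma_miRNA28": ("UCUGUACCAUAAUAUAAGAC", 20, 120, 40.0, -35.1,
                    -0.73, -29.25, 60.0),
    "Gma_miRNA29": ("UAGAUACAUCCAUAUGUAGA", 20, 120, 35.0, -34.4,
                    -0.81, -35.66, 65.0),
}

# Printed cells that are internally consistent with the row's own
# (length, GC%, MFE); the remaining cells are documented as inconsistent
# and are never asserted.
CONSISTENT_AMFE = ("Gma_miRNA12", "Gma_miRNA24", "Gma_miRNA26", "Gma_miRNA28")
CONSISTENT_MFEI = ("Gma_miRNA12", "Gma_miRNA26", "Gma_miRNA28")


@pytest.fixture(scope="session")
def mature_records():
    return [SequenceRecord(mid, seq, "rna") for mid, seq in PATHWAY_MATURES.items()]


@pytest.fixture(scope="session")
def builtin_engine():
    return BuiltinFoldEngine()


@pytest.fixture(scope="session")
def fold_engine():
    """Preferred engine: thermodynamic when available, else builtin."""
    return get_engine("auto")
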