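import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acp_ada.io import ALPHABET, PeptideRecord, PropertyTable, default_property_table

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: Ten deterministic peptides with hand-verifiable encodings.
GOLDEN = [
    # (id, sequence, label)
    ("g01", "ACDEFGH", 1),                   # BPF ones at 20i + i for i<7
    ("g02", "AAAA", 0),                      # AAC: pure alanine
    ("g03", "ACCA", 1),                      # AAC: A=C=0.5
    ("g04", "ACDEFGHIKLMNPQRSTVWY", 0),      # each residue once -> all 0.05
    ("g05", "KKKKKKKKKK", 1),                # pure lysine, cationic
    ("g06", "EEEEEEEE", 0),                  # pure glutamate, acidic
    ("g07", "KRKRKRKRKRKR", 1),              # alternating K/R
    ("g08", "GGGGSSSSGGGG", 0),              # flexible linker-like
    ("g09", "FLFLFLFLAA", 1),                # hydrophobic
    ("g10", "DEDEDEDEST", 0),                # acidic/polar
]


@pytest.fixture
def golden_records() -> list[PeptideRecord]:
    return [PeptideRecord(id=i, sequence=s, label=y) for i, s, y in GOLDEN]


@pytest.fixture(scope="session")
def property_table() -> PropertyTable:
    return default_property_table()


@pytest.fixture
def toy_table() -> PropertyTable:
    """Two toy properties: p_const is 1.0 everywhere, p_rank is the
    alphabet position (0..19) of the residue."""
    values = np.vstack([np.ones(20), np.arange(20, dtype=float)])
    return PropertyTable(("p_const", "p_rank"), values)
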