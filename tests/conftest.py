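import pytest

from dnabind.io import packaged_noe_table, packaged_sequences
from dnabind.restraints import parse_noe_table

#: Palindromic study sequences: 9 duplexes covering all dinucleotide steps
#: plus the 4 NTAN-site octamers.
STEP_SURVEY_IDS = [f"D{i}" for i in range(1, 10)]
NTAN_IDS = ["B1", "B2", "B3", "B4"]

#: Dissociation-constant grid (uM) used as simulation ground truths; the
#: 0.034 value is the sparse-data case (near-total binding at these ratios).
KD_GRID = [0.034, 0.145, 0.156, 0.227, 0.248, 0.260, 0.524, 0.608]
SPARSE_KD = 0.034


@pytest.fixture(scope="session")
def sequences() -> dict[str, str]:
    return dict(packaged_sequences())


@pytest.fixture(scope="session")
def table2_contacts():
    return parse_noe_table(packaged_noe_table("table2"))


@pytest.fixture(scope="session")
def table4_contacts():
    return parse_noe_table(packaged_noe_table("table4"))
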