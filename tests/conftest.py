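import pytest

from rnacad.rna_chem import parse_sequence
from rnacad.synth import STUDY_SEQUENCES

#: Printed monoisotopic masses (Da) of the fourteen study RNAs.
TABLE1_MASSES = {
    "RNA1": 4835.718,
    "RNA2": 4834.723,
    "RNA3": 4833.727,
    "RNA4": 4834.723,
    "RNA5": 4834.723,
    "RNA6": 4819.724,
    "RNA7": 4811.707,
    "RNA8": 4810.712,
    "RNA9": 4810.712,
    "RNA10": 4810.712,
    "RNA11": 4810.712,
    "RNA12": 4810.712,
    "RNA13": 4810.712,
    "RNA14": 4795.712,
}


@pytest.fixture(scope="session")
def rna1():
    return parse_sequence(STUDY_SEQUENCES["RNA1"])


@pytest.fixture(scope="session")
def rna2():
    return parse_sequence(STUDY_SEQUENCES["RNA2"])


@pytest.fixture(scope="session")
def rna6():
    return parse_sequence(STUDY_SEQUENCES["RNA6"])


@pytest.fixture(scope="session")
def all_rnas():
    return {name: parse_sequence(seq) for name, seq in STUDY_SEQUENCES.items()}
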