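import numpy as np
import pytest

from cancerlect.physchem import AMINO_ACIDS
from cancerlect.seqio import NEGATIVE, POSITIVE, ProteinRecord


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture(scope="session")
def random_records():
    """25 random records of length 40-120, fixed seed."""
    rng = np.random.default_rng(20240917)
    records = []
    for i in range(25):
        length = int(rng.integers(40, 121))
        records.append(ProteinRecord(f"r{i}", random_sequence(rng, length)))
    return records


@pytest.fixture(scope="session")
def toy_labelled_records():
    """Small labelled set with an easy composition signal (positives A-rich)."""
    rng = np.random.default_rng(7)
    records = []
    probs_pos = np.full(20, 0.03)
    probs_pos[0] = 1 - 0.03 * 19  # heavy A
    for i in range(15):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=60, p=probs_pos))
        records.append(ProteinRecord(f"p{i}", seq, POSITIVE))
    for i in range(15):
        records.append(ProteinRecord(f"n{i}", random_sequence(rng, 60), NEGATIVE))
    return records
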