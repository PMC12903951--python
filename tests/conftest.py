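from __future__ import annotations

import random

import pytest

from ontprep.schema import APSchema
from ontprep.seqio import SequenceRecord

BASES = "ACGT"


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def make_record(read_id: str, sequence: str, q: int = 20,
                comment: str | None = None) -> SequenceRecord:
    return SequenceRecord(read_id, sequence, [q] * len(sequence), comment)


@pytest.fixture(scope="session")
def schema() -> APSchema:
    """Synthetic 25 nt AP pair; matches the simulator's schema."""
    from ontprep.simulate import example_schema
    return example_schema()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(1234)
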