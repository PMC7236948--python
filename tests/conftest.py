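import numpy as np
import pytest

from phbrkit.peptides import TranscriptRecord
from phbrkit.scoring import HlaGenotype


@pytest.fixture
def toy_transcript() -> TranscriptRecord:
    # ATG GCC AAA CTG TAA -> MAKL
    return TranscriptRecord(transcript_id="TX1", cds="ATGGCCAAACTGTAA")


@pytest.fixture
def het_genotype() -> HlaGenotype:
    return HlaGenotype.from_names(
        ["A*01:01", "A*02:01", "B*07:02", "B*08:01", "C*04:01", "C*07:01"]
    )


@pytest.fixture
def hom_genotype() -> HlaGenotype:
    return HlaGenotype.from_names(
        ["A*01:01", "A*01:01", "B*07:02", "B*07:02", "C*04:01", "C*04:01"]
    )


class ConstantOracle:
    def __init__(self, value: float):
        self.value = value

    def rank(self, allele, peptide):
        return self.value


class DictOracle:
    """Rank oracle backed by an explicit dict; missing pairs get a default."""

    def __init__(self, table, default=50.0):
        self.table = table
        self.default = default

    def rank(self, allele, peptide):
        return self.table.get((allele.name, peptide), self.default)


@pytest.fixture
def constant_oracle():
    return ConstantOracle


@pytest.fixture
def dict_oracle():
    return DictOracle


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
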