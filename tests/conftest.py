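import numpy as np
import pytest

from neomerkit import Genome, build_kmer_index
from neomerkit.kmers import BASES


@pytest.fixture
def toy_genome():
    return Genome({"chr1": "ACGTACGTAA"}, assembly_label="toy")


@pytest.fixture
def toy_index_forward(toy_genome):
    return build_kmer_index(toy_genome, 4, canonical=False)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
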