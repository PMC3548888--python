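import numpy as np
import pytest
from hypothesis import settings

from minuniq.genome_index import build_index

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


def random_genome(rng: np.random.Generator, lengths: dict) -> dict:
    return {
        name: "".join(rng.choice(list("ACGT"), size=n))
        for name, n in lengths.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20130118)


@pytest.fixture
def small_genome(rng):
    """A 400 bp chromosome with a planted 60 bp duplication."""
    seqs = random_genome(rng, {"chr1": 400})
    s = seqs["chr1"]
    seqs["chr1"] = s[:300] + s[100:160] + s[360:]
    return seqs


@pytest.fixture
def small_index(small_genome):
    return build_index(small_genome)
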