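import numpy as np
import pytest

from endosym import simulate


@pytest.fixture(scope="session")
def symbiont_source():
    return simulate.CompositionSource.from_gc(0.25, "symbiont", seed=2)


@pytest.fixture(scope="session")
def host_source():
    return simulate.CompositionSource.from_gc(0.48, "host", seed=1)


@pytest.fixture(scope="session")
def small_genome(symbiont_source):
    """A 200 kb symbiont-like genome reused by annotation/HGT/stats tests."""
    return simulate.gen_genome(symbiont_source, 200_000, seed=11, contig_id="sim")


@pytest.fixture(scope="session")
def small_annotation(small_genome):
    annotation, truth = simulate.gen_annotation(small_genome, seed=11)
    return annotation, truth


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
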