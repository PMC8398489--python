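import numpy as np
import pytest

from viromesig.simulate import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def genome_4k():
    return make_genome(GenomeSpec(segment_lengths=(4000,), gc_fraction=0.5, seed=101))


@pytest.fixture(scope="session")
def genome_2seg():
    return make_genome(GenomeSpec(segment_lengths=(1500, 900), gc_fraction=0.45,
                                  seed=202))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
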