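import numpy as np
import pytest

from genomesurvey.simulate import simulate_diploid_genome


@pytest.fixture(scope="session")
def small_diploid():
    """100-kb diploid genome with 1% heterozygosity."""
    return simulate_diploid_genome(100_000, 0.01, seed=101)


@pytest.fixture(scope="session")
def haploid_genome():
    """100-kb genome with no heterozygosity (both haplotypes identical)."""
    return simulate_diploid_genome(100_000, 0.0, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
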