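import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cinscape.genome_model import build_layout, toy_layout
from cinscape.profiles import PopulationMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20210930)


@pytest.fixture
def toy():
    """Two chromosomes, 10 bins of 1 Mb each."""
    return toy_layout(n_chrom=2, bins_per_chrom=10)


@pytest.fixture
def one_chrom_10mb():
    """Single 10-bin chromosome of 1 Mb bins (hand-checkable scores)."""
    return build_layout([("chr1", 10_000_000)], bin_size=1_000_000)


def random_toy_population(layout, n_cells, rng, max_state=4):
    matrix = rng.integers(0, max_state + 1, size=(n_cells, layout.n_bins))
    return PopulationMatrix(layout=layout, matrix=matrix.astype(np.int16))
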