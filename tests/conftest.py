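import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from syndel.simulate import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A compact two-chromosome genome shared by read-only tests."""
    return generate_genome(SimulationConfig(seed=11, n_chromosomes=2,
                                            genes_per_chromosome=200))


@pytest.fixture(scope="session")
def medium_genome():
    """The standard synthetic genome for recovery-style checks."""
    return generate_genome(SimulationConfig(seed=7, n_chromosomes=2,
                                            genes_per_chromosome=1000))
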