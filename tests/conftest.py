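import numpy as np
import pytest

from sptumor import load_table1
from sptumor.simulate import SimulationConfig, simulate_reference


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def reference():
    """One shared synthetic genome (22 autosomes + X/Y, ~3.4 Mb)."""
    return simulate_reference(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def small_reference():
    """Two-chromosome mini genome for cheap per-test simulations."""
    full = simulate_reference(SimulationConfig(seed=102, genome_scale=0.3))
    return {"chr1": full["chr1"], "chr2": full["chr2"]}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
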