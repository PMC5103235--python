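import numpy as np
import pytest

from allomap import Direction, SimulationSpec, simulate_dataset
from allomap.likelihood import FitConfig, PhenotypeMatrix
from allomap.simulate import QtlEffect

#: Intercross QTL with a clear additive displacement of the height-scaling
#: coefficient a; used wherever a detectable locus is needed.
STRONG_QTL = QtlEffect(0, {0: (2.85, 1.0), 1: (3.0, 1.0), 2: (3.15, 1.0)})


@pytest.fixture(scope="session")
def small_dataset():
    """64 progeny x 8 ages, 12 SNPs, one strong planted intercross QTL."""
    spec = SimulationSpec(n_progeny=64, T=8, n_snps=12, qtls=[STRONG_QTL], seed=42)
    snps, pairs = simulate_dataset(spec)
    return spec, snps, pairs


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    _, _, pairs = small_dataset
    return PhenotypeMatrix.from_pairs(pairs)


@pytest.fixture
def fast_fit_config():
    return FitConfig(n_restarts=2, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
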