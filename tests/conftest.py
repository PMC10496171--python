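import numpy as np
import pytest

from ebcomp.config import SimulationConfig
from ebcomp import preprocess as pp
from ebcomp import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, n_celltypes=2,
                            n_cells_per_sample=25,
                            baseline_logmean_range=(-1.0, 1.0), seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sim.simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_study(small_truth, small_config):
    return sim.simulate_species_cells(small_truth, small_config)


@pytest.fixture(scope="session")
def small_pseudobulk(small_study):
    return pp.make_pseudobulk(small_study.counts, small_study.cell_meta,
                              small_study.truth.genes)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
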