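import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from nbtme import CountMatrix, LogNormMatrix, lognormalize, presets, simulate_tme

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_lognorm(values: np.ndarray, genes=None, cells=None) -> LogNormMatrix:
    """Wrap a dense gene x cell array as a LogNormMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return LogNormMatrix(pd.DataFrame(values, index=genes, columns=cells))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_counts(rng) -> CountMatrix:
    dense = rng.poisson(2.0, size=(20, 15))
    dense[0, :] += 1  # avoid zero-total cells
    return CountMatrix(sp.csr_matrix(dense),
                       [f"g{i:02d}" for i in range(20)],
                       [f"c{j:02d}" for j in range(15)])


@pytest.fixture(scope="session")
def benchmark_sim():
    """One paired-species benchmark simulation shared across tests."""
    config = presets.xspecies_benchmark(seed=0)
    return config, simulate_tme(config)


@pytest.fixture(scope="session")
def benchmark_lognorms(benchmark_sim):
    _config, result = benchmark_sim
    return {sp_: lognormalize(result.counts[sp_]) for sp_ in result.counts}


@pytest.fixture(scope="session")
def cohort_small():
    """Reduced-size paired cohort with canonical marker symbols."""
    config = presets.mouse_human_cohort(
        seed=11, mouse_cells_per_sample=250, human_cells_per_sample=150
    )
    return config, simulate_tme(config)
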