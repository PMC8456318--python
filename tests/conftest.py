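import numpy as np
import pandas as pd
import pytest

from acidpipe import expression_profiles as ep
from acidpipe import integration
from acidpipe import synthetic_data as sd
from acidpipe.io_core import CountMatrix, RunConfig


@pytest.fixture(scope="session")
def default_spec():
    return sd.SimulationSpec(rng_seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    return sd.generate_dataset(default_spec)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_result(default_dataset, default_config):
    return integration.run_full_pipeline(default_dataset, default_config)


def nb_draw(rng, mean, alpha, size=None):
    """Independent NB sampler for test fixtures (mean/dispersion form)."""
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def toy_count_matrix(values, sample_prefix="s"):
    arr = np.asarray(values)
    df = pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
    )
    return CountMatrix(counts=df, totals=df.sum(axis=0).astype(float))
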