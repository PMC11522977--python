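import logging

import numpy as np
import pandas as pd
import pytest

from cutinet import synthdata as sd
from cutinet.containers import OmicsMatrix

logging.getLogger("cutinet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    return sd.default_config(
        seed=1,
        n_genes=300,
        n_modules=2,
        module_sizes=(60, 40),
        n_metabolites_per_fraction=24,
        n_assoc_genes=6,
        n_assoc_both=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sd.generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(values, prefix="f", samples=None) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    features = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=features, columns=samples))
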