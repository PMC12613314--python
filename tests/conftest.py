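import numpy as np
import pandas as pd
import pytest

from edcorr.features import FEATURE_COLUMNS
from edcorr.library import train_library
from edcorr.router import train_router
from edcorr.simulate import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_world():
    """A modest 5-class synthetic world plus its ground truth."""
    table, truth = generate_dataset(SynthConfig(n_per_class=60, noise_sd=0.5, seed=7))
    return table, truth


@pytest.fixture(scope="session")
def default_world():
    """The standard study conditions: 300 reactions/class, 0.5 kcal/mol noise."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_library(small_world):
    table, _ = small_world
    library, reports = train_library(table, ("PBE", "def2-TZVP"), split_report=False)
    return library, reports


@pytest.fixture(scope="session")
def small_router(small_world):
    table, _ = small_world
    return train_router(table, seed=3, tree_grid=(50, 100), depth_grid=(8, None))


def random_feature_table(rng, n, with_refs=True):
    """Unstructured random descriptor rows for low-level model tests."""
    data = {"reaction_id": [f"r{i}" for i in range(n)]}
    for col in FEATURE_COLUMNS:
        data[col] = rng.normal(0.0, 5.0, size=n)
    data["superset"] = [None] * n
    table = pd.DataFrame(data)
    if with_refs:
        table["ref_energy"] = rng.normal(0.0, 20.0, size=n)
        # keep percentage errors defined
        small = table["ref_energy"].abs() < 0.5
        table.loc[small, "ref_energy"] = 0.5 * np.sign(table.loc[small, "ref_energy"]) + \
            (table.loc[small, "ref_energy"] == 0) * 0.5
    else:
        table["ref_energy"] = None
    return table
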