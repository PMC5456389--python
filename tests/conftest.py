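import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from denpipe.io_formats import FoldChangeMatrix
from denpipe.synthetic_data import fixture_config, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """50-gene, 20-sample synthetic dataset shared across unit tests."""
    return generate_dataset(fixture_config("tiny", seed=11))


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory, tiny_dataset):
    """The tiny dataset written to disk in every external dialect."""
    from denpipe.synthetic_data import write_dataset

    outdir = tmp_path_factory.mktemp("tiny_fixture")
    write_dataset(tiny_dataset, outdir)
    return outdir


@pytest.fixture()
def small_matrix():
    frame = pd.DataFrame(
        [[0.70, -0.80, 0.50], [0.69, 0.0, np.nan], [-0.69, -0.70, 1.2]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3"],
    )
    return FoldChangeMatrix(frame)


def random_matrix(rng, n_probes, n_samples, missing_rate=0.05):
    values = rng.normal(0.0, 0.8, size=(n_probes, n_samples))
    # sprinkle values at/near the default cutoffs to exercise strictness
    boundary = rng.random(values.shape) < 0.05
    values[boundary] = rng.choice([0.69, -0.69, 0.6900000001, -0.6900000001],
                                  size=int(boundary.sum()))
    missing = rng.random(values.shape) < missing_rate
    values[missing] = np.nan
    return FoldChangeMatrix(pd.DataFrame(
        values,
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    ))
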