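import numpy as np
import pytest

from pinets.benchmarks import experiment_spec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def cubic_dataset():
    """The univariate cubic study data: 200 points on [-1.25, 1.25] with
    additive N(0, 9) noise (one fixed seed for the whole session)."""
    ds = generate_dataset(experiment_spec("cubic", seed=989))
    x = ds.replicates[0].times
    y = ds.replicates[0].states[:, 0]
    return ds, x, y


@pytest.fixture(scope="session")
def lv_truth():
    """Noiseless Lotka-Volterra trajectory at study settings."""
    return generate_dataset(
        experiment_spec("lotka_volterra", noise_sd=0.0, replicates=1, seed=0)
    )
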