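import numpy as np
import pandas as pd
import pytest

from tnbcsig import CohortConfig, generate_cohort, generate_signature_registry


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_samples=60, n_genes=240, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_registry(small_config):
    return generate_signature_registry(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def blob_features():
    """Three well-separated Gaussian blobs (multivariate separation: every
    cluster pair differs by >= 6 SD across several features, the geometry the
    generator's signature blocks produce) plus one noise categorical."""
    rng = np.random.default_rng(5)
    n_per = 40
    centers = np.zeros((3, 9))
    for c in range(3):
        centers[c, 3 * c:3 * c + 3] = 5.0
    rows = [rng.normal(centers[c], 1.0, size=(n_per, centers.shape[1]))
            for c in range(3)]
    x = np.vstack(rows)
    df = pd.DataFrame(x, columns=[f"f{j}" for j in range(centers.shape[1])],
                      index=[f"s{i}" for i in range(3 * n_per)])
    df["cat"] = pd.Categorical(rng.choice(["a", "b"], size=3 * n_per))
    labels = np.repeat(np.arange(1, 4), n_per)
    return df, labels
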