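import numpy as np
import pytest

from myotex.phantom import CohortConfig, PhantomConfig, generate_lv_phantom


@pytest.fixture(scope="session")
def small_phantom_config():
    """A fast noise-on phantom on a reduced grid."""
    return PhantomConfig(
        grid_shape=(32, 32, 16),
        shell_radii_inner=(7.0, 7.0, 4.0),
        shell_radii_outer=(12.0, 12.0, 7.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return generate_lv_phantom(small_phantom_config)


@pytest.fixture(scope="session")
def toy_volume_mask():
    """A 4x4x4 random integer volume with a random (nonempty) mask."""
    rng = np.random.default_rng(42)
    vol = rng.integers(0, 30, size=(4, 4, 4)).astype(float)
    mask = rng.random((4, 4, 4)) > 0.25
    mask[1, 1, 1] = True
    return vol, mask


@pytest.fixture(scope="session")
def planted_gauss_table():
    """A strongly class-separated Gaussian feature table, 24/12/16 split."""
    from myotex.selection import FeatureTable

    rng = np.random.default_rng(5)
    labels = np.repeat([1, 2, 3], [24, 12, 16])
    centers = rng.normal(0, 2.0, (3, 10))
    X = np.vstack([rng.normal(centers[l - 1], 0.6, (1, 10))[0]
                   for l in labels]).reshape(52, 10)
    X = np.column_stack([X, rng.standard_normal((52, 10))])
    names = [f"sig{i}" for i in range(10)] + [f"noise{i}" for i in range(10)]
    return FeatureTable(X, names, labels)
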