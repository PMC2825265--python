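import numpy as np
import pytest

from ethoproto import (
    FeatureMatrix,
    default_artificial_spec,
    gaussian_mixture,
    znormalize,
)


@pytest.fixture(scope="session")
def artificial():
    """Five-cloud 2-D benchmark: (normalized FeatureMatrix, true labels, spec)."""
    spec = default_artificial_spec(n=500, seed=1)
    fm, labels = gaussian_mixture(spec)
    return znormalize(fm), labels, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def feature_matrix(values, names=None):
    values = np.asarray(values, float)
    names = tuple(names) if names else tuple(f"f{i}" for i in range(values.shape[1]))
    return FeatureMatrix(values, names, tuple("" for _ in names))
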