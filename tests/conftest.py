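import numpy as np
import pytest

from pallor.kalman import FeatureSeries
from pallor.synthetic import SyntheticSpec, generate_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_series():
    """Noise-free series exactly on feature = 60 + 8*hb."""
    hb = np.linspace(6.0, 16.0, 30)
    return FeatureSeries(hb=hb, z=60.0 + 8.0 * hb)


@pytest.fixture
def noisy_table():
    """Feature-level synthetic dataset at the default study conditions."""
    return generate_feature_table(SyntheticSpec(n_subjects=100, seed=42))
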