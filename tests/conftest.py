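import numpy as np
import pytest

from mmgsel.features import build_feature_matrix
from mmgsel.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mmg_config():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def mmg_segments(mmg_config):
    """Default synthetic dataset: 4 classes x 100 reps through the real
    preprocessing path.  Session-scoped — generation plus feature
    extraction is the expensive part of the suite."""
    return generate_dataset(mmg_config)


@pytest.fixture(scope="session")
def mmg_features(mmg_config, mmg_segments):
    return build_feature_matrix(mmg_segments, mmg_config.fs)
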