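import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from helixcycle import ExpressionMatrix, Scale


@pytest.fixture
def small_matrix():
    """3 genes x 4 cells of counts with handy round numbers."""
    values = np.array([
        [0.0, 3.0, 7.0, 1.0],
        [2.0, 0.0, 0.0, 0.0],
        [5.0, 5.0, 5.0, 5.0],
    ])
    return ExpressionMatrix(values, ["g1", "g2", "g3"],
                            ["c1", "c2", "c3", "c4"], Scale.counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
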