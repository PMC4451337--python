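import numpy as np
import pytest

from bcistate.synthetic import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


@pytest.fixture
def small_config():
    """Two-participant cohort small enough for per-test generation."""
    return GeneratorConfig(n_participants=2, n_online_sessions=1,
                           intersections_per_session=15, seed=123)
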