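import numpy as np
import pytest

from improdyn.experiments import era_separation_medians


@pytest.fixture(scope="session")
def era_separation_scores():
    """5-run median era-separation scores for pitch vs rhythm streams.

    Session-scoped: the end-to-end property and the acceptance check share
    one computation.
    """
    return era_separation_medians(seed=2025, n_runs=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
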