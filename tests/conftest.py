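import logging

import numpy as np
import pytest

from ctdseq import pipeline
from ctdseq.synthetic import SimConfig

logging.getLogger("ctdseq").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition simulated genome shared across test modules."""
    return pipeline.build_bundle(SimConfig(seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
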