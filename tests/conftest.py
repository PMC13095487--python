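import logging

import numpy as np
import pytest

from fiberkit.experiments import make_clean_slide
from fiberkit.pipeline import PipelineConfig

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def clean_slide():
    """Small noiseless crossing-free slide with planted truth (session-wide)."""
    return make_clean_slide(20, (512, 512), seed=101)


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
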