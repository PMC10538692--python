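import numpy as np
import pytest
from hypothesis import settings

from amcascade import SynthSpec, generate, pad_cascade, zscore_normalize
from amcascade.synth import LevelSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nested_sample():
    """One nested-AM synthetic sample at the canonical rates/depths."""
    spec = SynthSpec(
        duration_s=10.0,
        rate_hz=4000.0,
        prosody=LevelSpec(2.0, 0.8),
        syllable=LevelSpec(6.0, 0.6),
        phoneme=LevelSpec(20.0, 0.4),
        seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def nested_hierarchy(nested_sample):
    """Cascade output for the shared nested-AM sample."""
    return pad_cascade(zscore_normalize(nested_sample.sample))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
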