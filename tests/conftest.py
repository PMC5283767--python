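import numpy as np
import pytest

from resistsim import config as cfg


@pytest.fixture
def curtis_cal():
    """Idealised calibration, starts (0.01, 0.001)."""
    return cfg.curtis_idealised()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_genotype_frequencies(rng, strictly_positive=False):
    """A random valid per-sex genotype-frequency table."""
    raw = rng.random((2, 10))
    if strictly_positive:
        raw += 0.01
    return raw / raw.sum(axis=1, keepdims=True)
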