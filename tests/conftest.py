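import numpy as np
import pytest

from spinecodec.phantom import PhantomSpec, generate_dataset


def tiny_spec_kwargs():
    """Desk-scale model size used throughout the suite."""
    return dict(depth=3, base_channels=8)


@pytest.fixture(scope="session")
def phantom_fixture():
    """The fixed overfit fixture: 16 noise-sigma=0.03 phantoms, 64x64, seed 0."""
    pairs, _ = generate_dataset(
        16, PhantomSpec(size=(64, 64), noise_sigma=0.03), seed=0)
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
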