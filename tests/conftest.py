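import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240211)


@pytest.fixture(scope="session")
def small_fixture():
    """Tiny synthetic image set for fast training tests (3 classes, 32 px)."""
    from fruitnet.data import FixtureSpec, generate_fixture

    return generate_fixture(FixtureSpec(num_classes=3, images_per_class=6,
                                        image_size=32, seed=11))


@pytest.fixture(scope="session")
def small_model():
    """Small-input build of the full architecture (3 classes, 32 px)."""
    from fruitnet.model import build_model, default_architecture

    return build_model(default_architecture(3, (32, 32)), seed=5)
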