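import numpy as np
import pytest

from bresym.phantom import PhantomSpec, generate_phantom_dataset


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse, fast phantom dataset for unit tests (the acceptance experiment
    runs the full-resolution conditions itself)."""
    return generate_phantom_dataset(
        seed=3,
        image_spacing_mm=4.535,
        gt_spacing_mm=9.07,
        n_landmarks=100,
        gt_max_steps=20000,
    )


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
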