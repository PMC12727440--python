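import numpy as np
import pytest

from lesionbench.phantom import PhantomSpec, make_template


@pytest.fixture(scope="session")
def spec48():
    return PhantomSpec(grid_shape=(48, 48, 48), n_roi_pairs=8, noise_sd=5.0, seed=11)


@pytest.fixture(scope="session")
def template48(spec48):
    """Noisy-spec template triple on a 48^3 grid (template itself is noise-free)."""
    return make_template(spec48)


@pytest.fixture(scope="session")
def clean48():
    """Zero-noise spec and template for exactness anchors."""
    spec = PhantomSpec(grid_shape=(48, 48, 48), n_roi_pairs=8, noise_sd=0.0, seed=11)
    return spec, make_template(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
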