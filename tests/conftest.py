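import numpy as np
import pytest

from occtkit.phantom import CLASSES, PhantomSpec, render_array_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(label="NORMAL", seed=0, **kw):
    """A 64x64 phantom spec scaled down for fast tests."""
    defaults = dict(height=64, width=64, curvature=3.0, lesion_radius=6.0,
                    border_width=4, speckle_sigma=0.05)
    defaults.update(kw)
    return PhantomSpec(label=label, seed=seed, **defaults)


@pytest.fixture(scope="session")
def phantom_bank():
    """40 small phantoms per class, rendered once per session."""
    spec = small_spec()
    imgs, labels = render_array_dataset({c: 40 for c in CLASSES}, base_seed=7,
                                        spec_template=spec)
    return imgs, labels
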