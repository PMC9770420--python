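import numpy as np
import pytest

from wpbquant.segmentation import count_field
from wpbquant.synthetic import SceneSpec, render_field

SMALL_SCENE = dict(
    field_width_px=320,
    field_height_px=320,
    n_slices=5,
    nucleus_count=5,
    nucleus_radius_um=(3.0, 5.0),
    wpb_count=25,
    immature_count=8,
    noise_sd=10.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_field():
    """A small rendered field with ground truth, reused across tests."""
    spec = SceneSpec(**SMALL_SCENE)
    image, truth = render_field(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_field_counts(small_field):
    _, image, _ = small_field
    return count_field(image)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
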