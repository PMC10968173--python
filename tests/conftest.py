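import numpy as np
import pytest

from tbtoa.cohort import CohortSpec, generate_cohort
from tbtoa.fbm import FbmSpec, generate_fbm_surface
from tbtoa.labels import label_cohort
from tbtoa.texture import build_roi_layout


@pytest.fixture(scope="session")
def layout_2x8():
    """Default 2x8 patchwork on a 64x256 px tibial bounding box."""
    return build_roi_layout((0, 0, 64, 256))


@pytest.fixture(scope="session")
def fbm_half():
    """One 256-px fractional Brownian surface with H = 0.5."""
    return generate_fbm_surface(FbmSpec(hurst=0.5, size_px=256, seed=11))


@pytest.fixture(scope="session")
def labelled_cohort():
    """A mid-size labelled synthetic cohort shared across tests."""
    return label_cohort(generate_cohort(CohortSpec(n_knees=400, seed=3)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
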