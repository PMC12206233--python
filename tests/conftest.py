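import numpy as np
import pytest

from natpipe.atlas import synthetic_atlas
from natpipe.synthetic import CohortConfig

SMALL_SIZES = {"SMN": 6, "DMN": 8, "FPN": 5, "ATN": 4}


@pytest.fixture(scope="session")
def ref_atlas():
    """Reference 300-ROI atlas with the study subnetwork sizes."""
    return synthetic_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    """Scaled-down 30-ROI atlas for fast end-to-end runs."""
    return synthetic_atlas(sizes=SMALL_SIZES, n_rois=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def study_config():
    """Generator settings at the study's group sizes."""
    return CohortConfig(seed=11)


def random_connectivity(n, rng):
    """Random symmetric zero-diagonal matrix on the Fisher-z scale."""
    w = rng.normal(scale=0.4, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
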