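import numpy as np
import pytest

from bodymap.body_model import BodyView, OutlineMask, SymptomMap, VIEWS
from bodymap.synthetic_cohort import PerturbParams, SimParams, generate_outline_set

SMALL_DIMS = (160, 100)


@pytest.fixture(scope="session")
def outlines_small():
    """Four-view outline set on a small canvas, shared across tests."""
    return generate_outline_set(SMALL_DIMS)


@pytest.fixture()
def small_params():
    """Cohort parameters scaled to the small canvas for fast simulation."""
    return SimParams(
        n_patients=5,
        outline_dims=SMALL_DIMS,
        clusters_per_view_mean=3.0,
        clusters_per_view_sd=3.0,
        blob_radius_median=5.0,
        blob_radius_sigma=0.4,
        perturb=PerturbParams(2.0, 1.0, 0.1, 0.1),
        seed=7,
    )


def make_map(view, dims, pixels, vas=5):
    """SymptomMap with the given (row, col) pixels set to ``vas``."""
    arr = np.zeros(dims, dtype=np.int16)
    for r, c in pixels:
        arr[r, c] = vas
    return SymptomMap(BodyView(view), arr)


def full_outlines(dims):
    """Outline set whose interior is the whole canvas (for geometry tests)."""
    return {v: OutlineMask(v, np.ones(dims, dtype=bool)) for v in VIEWS}
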