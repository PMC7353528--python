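import numpy as np
import pytest

from sensefuse import CohortConfig, simulate_cohort, fuse_cohort
from sensefuse import faceprep
from sensefuse.schematic import render_face


@pytest.fixture(scope="session")
def detector():
    """The lazily trained HoG detector, shared across tests."""
    return faceprep.get_default_detector()


@pytest.fixture(scope="session")
def fixture_face():
    """A clean, centred schematic face with ground-truth landmarks."""
    return render_face(size=200)


@pytest.fixture(scope="session")
def photo_like_face():
    """A shaded, blurred, noisy schematic render (synthetic stand-in for a
    photographic frontal-face fixture)."""
    return render_face(size=200, shading=True, blur_sigma=0.8, noise_sd=4,
                       rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant cohort (120 trials) used by fusion/report tests."""
    return simulate_cohort(CohortConfig(n_participants=12, seed=42))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return fuse_cohort(small_cohort.records)
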