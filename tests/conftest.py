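import numpy as np
import pytest

import echostrain as es


@pytest.fixture(scope="session")
def imaging():
    """Small desk-scale imaging geometry shared by the tracking tests."""
    return es.ImagingConfig(depth=8.0, lines=48)


@pytest.fixture(scope="session")
def speckle_pair(imaging):
    """Noiseless speckle frames with a pure (4 sample, 1 line) rigid shift."""
    motion = es.MotionModel.rigid_shift((4 * imaging.dz, imaging.pitch))
    scene = es.SceneConfig(imaging=imaging, motion=motion, n_frames=4,
                           snr_db=None, seed=3)
    seq, gt = es.generate_sequence(scene)
    return seq, gt


@pytest.fixture(scope="session")
def cyclic_scene():
    """Annular-wall scene used by the noise-robustness experiments."""
    imaging = es.ImagingConfig(depth=9.5, lines=52)
    motion = es.MotionModel.cyclic_wall(center=(10.5, 5.0), r_endo=3.5,
                                        r_epi=5.5, theta_span=(-0.65, 0.65),
                                        peak_radial_strain=0.08,
                                        peak_longitudinal_strain=-0.06,
                                        cycle_frames=12)
    return imaging, motion


def random_pdf_grid(rng, shape=(3, 3), lags=(9, 9)):
    """Random valid PDF grid over blocks x lags."""
    g = rng.random(shape + lags) + 1e-3
    return g / g.sum(axis=(-2, -1), keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


# deterministic hypothesis runs regardless of environment
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
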