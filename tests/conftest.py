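import numpy as np
import pytest

from photoprf.calibration import DisplayModel
from photoprf.prf import CoarsePredictor, double_gamma_hrf
from photoprf.spectra import gaussian_primary, standard_receptors
from photoprf.stimulus import ProtocolConfig, compose_run


@pytest.fixture(scope="session")
def protocol():
    # 2 px/deg analysis grid keeps multi-dataset simulations tractable
    return ProtocolConfig(grid_resolution=2.0)


@pytest.fixture(scope="session")
def apertures(protocol):
    return compose_run(protocol)


@pytest.fixture(scope="session")
def hrf():
    return double_gamma_hrf()


@pytest.fixture(scope="session")
def predictor(apertures, hrf):
    return CoarsePredictor(apertures, hrf)


@pytest.fixture(scope="session")
def receptors():
    return standard_receptors()


@pytest.fixture(scope="session")
def demo_display():
    return DisplayModel(
        primaries=(
            gaussian_primary(610.0),
            gaussian_primary(545.0),
            gaussian_primary(465.0),
        ),
        gamma=np.full(3, 2.2),
    )


def random_display(rng):
    """Random plausible three-primary display for property tests."""
    peaks = [rng.uniform(590, 630), rng.uniform(520, 560), rng.uniform(440, 480)]
    return DisplayModel(
        primaries=tuple(
            gaussian_primary(p, fwhm_nm=rng.uniform(20, 40), power=rng.uniform(0.5, 1.5))
            for p in peaks
        ),
        gamma=rng.uniform(1.8, 2.6, size=3),
        attenuation=rng.uniform(0.7, 1.0, size=3),
    )
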