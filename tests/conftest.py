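import numpy as np
import pytest

import deerwave as dw
from deerwave.fixtures import model_distribution, nitroxide_spectrum
from deerwave.spin_dynamics import SpinField


@pytest.fixture(scope="session")
def spectrum():
    return nitroxide_spectrum()


@pytest.fixture(scope="session")
def field30():
    return SpinField(nu1_max=30e6)


@pytest.fixture(scope="session")
def model_dist():
    """The study's model system: 5.1 nm mean, 0.2 nm FWHM."""
    return model_distribution()


@pytest.fixture(scope="session")
def calibration_dist():
    """A distribution whose dipolar oscillations decay within ~2 µs, used to
    validate estimators under their operating assumptions."""
    return model_distribution(4.0, 0.6)


def rabi_mz(nu1, offset, tp):
    """Closed-form final Mz of a rectangular pulse — the independent oracle."""
    nu_eff2 = nu1**2 + offset**2
    return 1 - 2 * (nu1**2 / nu_eff2) * np.sin(np.pi * np.sqrt(nu_eff2) * tp) ** 2
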