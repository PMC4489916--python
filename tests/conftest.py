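import numpy as np
import pytest

from cyclechrome import optics
from cyclechrome.optics import Spectrum


@pytest.fixture(scope="session")
def d65():
    return optics.load_standard_curves("d65")


@pytest.fixture(scope="session")
def lms():
    return optics.load_standard_curves("stockman_sharpe_lms")


@pytest.fixture(scope="session")
def xyz():
    return optics.load_standard_curves("cie1931_xyz")


@pytest.fixture
def unit_spectrum():
    return Spectrum(np.ones(optics.N_SAMPLES), kind="reflectance")


@pytest.fixture
def unit_sensitivities():
    return optics.SensitivitySet(
        ("A", "B", "C"), np.ones((3, optics.N_SAMPLES))
    )


@pytest.fixture
def gaussian_reflectance():
    lam = optics.WAVELENGTHS_NM
    return Spectrum(np.exp(-0.5 * ((lam - 550.0) / 30.0) ** 2),
                    kind="reflectance")
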