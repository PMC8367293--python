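import numpy as np
import pytest

import nadhtrf as nt


@pytest.fixture(scope="session")
def settings():
    return nt.AcquisitionSettings()


@pytest.fixture(scope="session")
def irf200(settings):
    return nt.gaussian_irf(settings, center=1000.0, fwhm=200.0)


@pytest.fixture(scope="session")
def irf35(settings):
    return nt.gaussian_irf(settings, center=1000.0, fwhm=35.0)


@pytest.fixture(scope="session")
def noise_free_free25(settings, irf200):
    """Exact expected curve for free NADH at 25 degC, 1e6 photons, 200 ps IRF."""
    scaled = nt.scale_to_budget(nt.FREE_NADH_25C, settings, 1e6)
    curve = nt.convolve_irf(nt.multiexp_curve(scaled, settings), irf200)
    return nt.DecayHistogram(counts=curve, settings=settings)
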