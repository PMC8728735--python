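import numpy as np
import pytest

from amorphkit.hn_fit import HNParams, eval_hn_loss
from amorphkit.spectra_io import LossSpectrum, SpectrumSet
from amorphkit.synthetic_data import (
    DEFAULT_VFT,
    SpectrumSimConfig,
    simulate_glassy_flanks,
    simulate_spectrum_set,
)

GLASSY_TEMPERATURES = (342.0, 344.0, 346.0, 348.0, 350.0)


@pytest.fixture(scope="session")
def default_ladder() -> SpectrumSet:
    """Noiseless supercooled ladder under the generator's default VFT law."""
    return simulate_spectrum_set(SpectrumSimConfig(noise_cv=0.0))


@pytest.fixture(scope="session")
def glassy_flanks() -> SpectrumSet:
    """Noiseless flank-only spectra within 10 K below the generating Tg."""
    return simulate_glassy_flanks(SpectrumSimConfig(noise_cv=0.0), GLASSY_TEMPERATURES)


@pytest.fixture(scope="session")
def generating_vft():
    return DEFAULT_VFT


def hn_spectrum(
    delta_eps=7.8,
    tau_hn=2e-3,
    a=0.85,
    b=0.55,
    sigma_over_eps0=0.0,
    f_lo=-1,
    f_hi=6,
    ppd=10,
    temperature=370.0,
) -> LossSpectrum:
    """Closed-form HN + conductivity spectrum on a log frequency grid."""
    freqs = np.logspace(f_lo, f_hi, ppd * (f_hi - f_lo) + 1)
    params = HNParams(delta_eps, tau_hn, a, b, sigma_over_eps0)
    return LossSpectrum(temperature, freqs, eval_hn_loss(params, 2 * np.pi * freqs))
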