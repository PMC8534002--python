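import numpy as np
import pytest

from hypermet.hp_mrs import AcquisitionConfig, fid_to_spectrum
from hypermet.synthetic_data import ExchangeParams, simulate_hp_dynamics


@pytest.fixture(scope="session")
def acq13c() -> AcquisitionConfig:
    """The dynamic ¹³C protocol: FA 25°, TR 2 s, 60 spectra, 2048 points,
    5 kHz sweep at 75.515 MHz."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def dynamics_default(acq13c):
    return simulate_hp_dynamics(ExchangeParams(kpl=0.05), acq13c)


def stack_noise_sd_for_snr(stack, target_snr: float) -> float:
    """Time-domain complex noise SD giving the requested *spectral* SNR for
    the tallest peak in the stack (noise SD in the spectrum is the
    time-domain SD times sqrt(n_points) under the unnormalized DFT)."""
    acq = stack.acq
    height = max(
        float(np.abs(fid_to_spectrum(stack.data[i], acq, zero_fill=2).real).max())
        for i in range(stack.n_acq))
    return height / (target_snr * np.sqrt(acq.n_points))
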