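import numpy as np
import pytest

from heartscales import CohortSpec


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small cohort used across tests: 8 channels, 2 x 10 s blocks."""
    return CohortSpec(n_per_group=2, n_channels=8, block_duration=10.0,
                      mean_hr=70.0, seed=123)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def ou_signal(tau: float, fs: float, duration: float,
              seed: int = 0, noise_sd: float = 0.0) -> np.ndarray:
    """Unit-variance OU (AR(1)) reference signal with optional white noise."""
    from scipy import signal

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    phi = np.exp(-1.0 / (fs * tau))
    x = signal.lfilter([np.sqrt(1 - phi ** 2)], [1.0, -phi],
                       rng.standard_normal(n + 2000))[2000:]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x
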