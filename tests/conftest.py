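"""Shared test configuration: deterministic hypothesis profile and fixtures."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def curve():
    from tropichron import gen_bomb_curve

    return gen_bomb_curve()


def fft_amplitude(x: np.ndarray, period: float) -> float:
    """Amplitude of the Fourier component of ``x`` at ``period`` (oracle).

    Uses the discrete Fourier transform at the frequency bin nearest to
    1/period; the series length is chosen in tests to be an integer
    multiple of the period so the bin is exact.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = int(round(n / period))
    coef = np.fft.rfft(x - x.mean())
    return 2.0 * np.abs(coef[k]) / n
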