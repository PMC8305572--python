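import numpy as np
import pytest

from nmrdecon.io import Spectrum1D


def lorentz(A, lam, x0, x):
    """Reference Lorentz line shape used as the ground truth in tests."""
    x = np.asarray(x, dtype=float)
    return A * lam / (lam**2 + (x - x0) ** 2)


def make_spectrum(intensity, ppm_max=10.0, ppm_min=0.0):
    """Build a Spectrum1D from a bare intensity vector on a default axis."""
    intensity = np.asarray(intensity, dtype=float)
    ppm = np.linspace(ppm_max, ppm_min, len(intensity))
    return Spectrum1D(ppm=ppm, intensity=intensity)


@pytest.fixture
def flat_axis():
    return make_spectrum


@pytest.fixture
def single_lorentzian(flat_axis):
    """A finely sampled isolated Lorentzian (A=1, λ=20 pts, x0=500, n=1000)."""
    x = np.arange(1000, dtype=float)
    y = lorentz(1.0, 20.0, 500.0, x)
    return flat_axis(y), (1.0, 20.0, 500.0)
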