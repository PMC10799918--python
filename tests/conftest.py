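import numpy as np
import pytest

from quenchbind import Spectrum, SpectrumKind, SimulationConfig, simulate_titration


def gaussian_spectrum(
    center=340.0,
    width=15.0,
    amplitude=1000.0,
    start=285.0,
    stop=450.0,
    step=1.0,
    kind=SpectrumKind.EMISSION,
):
    wl = start + step * np.arange(int(round((stop - start) / step)) + 1)
    vals = amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return Spectrum(kind, wl, vals)


@pytest.fixture
def gauss340():
    return gaussian_spectrum()


@pytest.fixture
def linear_series():
    """Noiseless Stern-Volmer titration with K_sv = 1.92e4 M^-1."""
    cfg = SimulationConfig(quenching_model="stern_volmer_linear", K_sv_M=1.92e4)
    return simulate_titration(cfg)


@pytest.fixture
def hill_series():
    """Noiseless one-site binding titration with K_a = 3897, n = 0.89."""
    cfg = SimulationConfig(quenching_model="hill_binding", K_a_M=3897.0, n_sites=0.89)
    return simulate_titration(cfg)


def ols_oracle(x, y):
    """Closed-form two-parameter OLS: slope, intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return slope, ym - slope * xm
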