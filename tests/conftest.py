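import numpy as np
import pytest

from eprtomo.optics import (
    BeamSpectrum,
    EffectiveOptics,
    Geometry,
    OpticalConstants,
    SpectralBand,
    effective_optics,
    make_bands,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def geometry():
    """Long-propagation high-energy setup (30 m, 28 um pixels)."""
    return Geometry(L=30.0, pixel=28e-6)


@pytest.fixture
def constants():
    """Bone-minus-ethanol-like optical constants, smooth power law."""
    return OpticalConstants.power_law(
        1.4e-7, 1.41e-10, 109.0, np.geomspace(20.0, 350.0, 60)
    )


@pytest.fixture
def mono_band(constants):
    d, b = constants(109.0)
    return [SpectralBand(f=1.0, omega=109.0, delta=d, beta=b)]


@pytest.fixture
def mono_optics(mono_band):
    b = mono_band[0]
    return EffectiveOptics(delta_av=b.delta, beta_av=b.beta, omega_av=b.omega)


@pytest.fixture
def flat_spec():
    e = np.linspace(60.0, 180.0, 61)
    return BeamSpectrum(e, np.ones_like(e))


@pytest.fixture
def poly_bands(flat_spec, constants):
    return make_bands(flat_spec, 5, constants)


@pytest.fixture
def poly_optics(poly_bands, constants):
    return effective_optics(poly_bands, constants)


def gaussian_blob(n, sigma, amplitude=1.0):
    yy, xx = np.indices((n, n), dtype=float)
    r2 = (yy - n / 2) ** 2 + (xx - n / 2) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma**2))
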