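"""Beam spectra, optical constants and the absorption->phase/intensity maps.

Single-distance propagation phase contrast treats the sample-exit wavefront
as an effective absorption image ``a(x, y)`` (natural-log scale, ``a = 0``
meaning full transmission) plus a phase proportional to it through the
delta/beta ratio of the dominant-gradient material pair.  A polychromatic
beam is discretized into contiguous equal-area spectral bands; each band
carries its own optical constants and attenuates/refracts the common
absorption variable with a band-dependent scale.

Units: photon energies in keV, lengths in metres, transverse shifts in
detector pixels.  Wavelength from energy via ``hc = 1.23984193 eV um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HC_KEV_M",
    "BeamSpectrum",
    "SpectralBand",
    "EffectiveOptics",
    "Geometry",
    "wavenumber",
    "equal_area_bands",
    "make_bands",
    "effective_optics",
    "phase_from_absorption",
    "band_fields",
    "confusion_width",
    "OpticalConstants",
    "load_spectrum",
]

#: hc in keV * m  (1.23984193 eV um)
HC_KEV_M = 1.23984193e-9


def wavenumber(energy_kev: float) -> float:
    """Vacuum wavenumber k = 2 pi / lambda (1/m) at the given photon energy."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return 2.0 * np.pi * energy_kev / HC_KEV_M


@dataclass(frozen=True)
class BeamSpectrum:
    """Effective (detected) spectral density on a strictly increasing energy grid."""

    energies: np.ndarray  # keV
    weights: np.ndarray  # arbitrary units, >= 0

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("spectrum needs at least 2 grid points")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if e.shape != w.shape:
            raise ValueError("energies and weights must have the same shape")
        if np.any(w < 0):
            raise ValueError("spectral weights must be non-negative")
        if np.trapezoid(w, e) <= 0:
            raise ValueError("total integrated spectral weight must be > 0")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @property
    def total_weight(self) -> float:
        return float(np.trapezoid(self.weights, self.energies))

    def mean_energy(self) -> float:
        """Weight-averaged photon energy over the whole grid (keV)."""
        return float(
            np.trapezoid(self.weights * self.energies, self.energies) / self.total_weight
        )


@dataclass(frozen=True)
class SpectralBand:
    """One discretized spectral subrange."""

    f: float  # fractional weight
    omega: float  # weighted-mean photon energy (keV)
    delta: float  # refractive index decrement at omega
    beta: float  # imaginary part of refractive index at omega

    def __post_init__(self):
        if not (0.0 < self.f <= 1.0):
            raise ValueError(f"band weight must be in (0, 1], got {self.f}")
        if self.delta <= 0 or self.beta <= 0:
            raise ValueError("optical constants delta, beta must be positive")

    @property
    def k(self) -> float:
        return wavenumber(self.omega)


@dataclass(frozen=True)
class EffectiveOptics:
    """Optical constants at the effective average beam energy."""

    delta_av: float
    beta_av: float
    omega_av: float  # keV

    def __post_init__(self):
        if self.delta_av <= 0 or self.beta_av <= 0:
            raise ValueError("effective optical constants must be positive")

    @property
    def ratio(self) -> float:
        return self.delta_av / self.beta_av

    @property
    def k(self) -> float:
        return wavenumber(self.omega_av)


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam propagation geometry."""

    L: float  # sample-to-detector propagation distance (m)
    pixel: float  # detector pixel size (m)
    n_rows: int = 0
    n_cols: int = 0

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("propagation distance L must be positive")
        if self.pixel <= 0:
            raise ValueError("pixel size must be positive")

    def rescaled(self, factor: int) -> "Geometry":
        """Geometry of a grid downsampled by ``factor`` (pixel size scaled up)."""
        return Geometry(
            L=self.L,
            pixel=self.pixel * factor,
            n_rows=-(-self.n_rows // factor) if self.n_rows else 0,
            n_cols=-(-self.n_cols // factor) if self.n_cols else 0,
        )


def _cumulative_weight(spectrum: BeamSpectrum) -> np.ndarray:
    """Cumulative trapezoid integral of the density on the grid, C[0] = 0."""
    e, w = spectrum.energies, spectrum.weights
    seg = 0.5 * (w[1:] + w[:-1]) * np.diff(e)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _invert_cumulative(spectrum: BeamSpectrum, target: float) -> float:
    """Energy at which the cumulative integral reaches ``target``.

    The density is piecewise linear, so each grid interval contributes a
    quadratic segment of the cumulative; invert that quadratic exactly.
    """
    e, w = spectrum.energies, spectrum.weights
    cum = _cumulative_weight(spectrum)
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(max(i, 0), e.size - 2)
    # solve 0.5*(w0 + w(t)) * t = rem on [e_i, e_i+1], density linear in t
    rem = target - cum[i]
    h = e[i + 1] - e[i]
    w0, w1 = w[i], w[i + 1]
    slope = (w1 - w0) / h
    if abs(slope) < 1e-30 * max(abs(w0), 1.0):
        t = rem / w0 if w0 > 0 else 0.0
    else:
        # 0.5*slope*t^2 + w0*t - rem = 0
        disc = w0 * w0 + 2.0 * slope * rem
        t = (-w0 + np.sqrt(max(disc, 0.0))) / slope
    return float(e[i] + min(max(t, 0.0), h))


def equal_area_bands(
    spectrum: BeamSpectrum, n_bands: int
) -> list[tuple[tuple[float, float], float, float]]:
    """Split the spectrum into contiguous subranges of equal integrated area.

    Returns one ``((e_lo, e_hi), f_i, omega_i)`` triple per band, where
    ``f_i = 1/n_bands`` and ``omega_i`` is the weight-averaged energy of the
    subrange.  The subranges cover the whole grid.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if n_bands > spectrum.energies.size - 1:
        raise ValueError(
            f"n_bands={n_bands} exceeds the number of grid intervals "
            f"({spectrum.energies.size - 1})"
        )
    total = spectrum.total_weight
    edges = [float(spectrum.energies[0])]
    for j in range(1, n_bands):
        edges.append(_invert_cumulative(spectrum, total * j / n_bands))
    edges.append(float(spectrum.energies[-1]))

    out = []
    for j in range(n_bands):
        lo, hi = edges[j], edges[j + 1]
        grid = np.unique(
            np.concatenate(
                [
                    [lo, hi],
                    spectrum.energies[
                        (spectrum.energies > lo) & (spectrum.energies < hi)
                    ],
                ]
            )
        )
        dens = np.interp(grid, spectrum.energies, spectrum.weights)
        area = np.trapezoid(dens, grid)
        omega = float(np.trapezoid(dens * grid, grid) / area)
        out.append(((lo, hi), 1.0 / n_bands, omega))
    return out


@dataclass(frozen=True)
class OpticalConstants:
    """Tabulated (delta, beta) versus photon energy for one material pair.

    Log-log interpolation between grid points; queries outside the tabulated
    range raise, they are never extrapolated.
    """

    energies: np.ndarray  # keV, strictly increasing
    delta: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        e = np.atleast_1d(np.asarray(self.energies, dtype=float))
        d = np.atleast_1d(np.asarray(self.delta, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(d <= 0) or np.any(b <= 0):
            raise ValueError("tabulated delta, beta must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "beta", b)

    def __call__(self, energy_kev: float) -> tuple[float, float]:
        e = self.energies
        if not (e[0] <= energy_kev <= e[-1]):
            raise ValueError(
                f"optical constants undefined at {energy_kev} keV "
                f"(tabulated range {e[0]}..{e[-1]} keV)"
            )
        if e.size == 1:
            return float(self.delta[0]), float(self.beta[0])
        le = np.log(e)
        x = np.log(energy_kev)
        d = np.exp(np.interp(x, le, np.log(self.delta)))
        b = np.exp(np.interp(x, le, np.log(self.beta)))
        return float(d), float(b)

    @classmethod
    def from_csv(cls, path) -> "OpticalConstants":
        arr = np.loadtxt(path, delimiter=",", comments="#")
        arr = np.atleast_2d(arr)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])

    @classmethod
    def power_law(
        cls,
        delta_ref: float,
        beta_ref: float,
        e_ref: float,
        e_grid: np.ndarray,
        delta_exp: float = -2.0,
        beta_exp: float = -3.5,
    ) -> "OpticalConstants":
        """Smooth synthetic table with power-law energy dependence.

        delta ~ E^-2 holds generally far from edges; beta falls faster
        (photoelectric ~E^-3.5; Compton flattens it at high energy).  Used by
        the phantom simulator, not a substitute for measured tables.
        """
        e = np.asarray(e_grid, dtype=float)
        return cls(
            e,
            delta_ref * (e / e_ref) ** delta_exp,
            beta_ref * (e / e_ref) ** beta_exp,
        )


def make_bands(
    spectrum: BeamSpectrum, n_bands: int, constants: OpticalConstants
) -> list[SpectralBand]:
    """Equal-area discretization with optical constants attached per band."""
    bands = []
    for (_lo, _hi), f, omega in equal_area_bands(spectrum, n_bands):
        d, b = constants(omega)
        bands.append(SpectralBand(f=f, omega=omega, delta=d, beta=b))
    return bands


def effective_optics(
    bands: list[SpectralBand], constants: OpticalConstants
) -> EffectiveOptics:
    """Optical constants at the effective average energy sum_i f_i omega_i."""
    fsum = sum(b.f for b in bands)
    if abs(fsum - 1.0) > 1e-9:
        raise ValueError(f"band weights must sum to 1, got {fsum}")
    omega_av = sum(b.f * b.omega for b in bands)
    d, b = constants(omega_av)
    return EffectiveOptics(delta_av=d, beta_av=b, omega_av=omega_av)


def phase_from_absorption(a: np.ndarray, optics: EffectiveOptics) -> np.ndarray:
    """Effective wavefront phase phi = -(delta_av/beta_av) * a / 2 (radians)."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("absorption map must be finite")
    return -(optics.ratio) * a / 2.0


def band_scale(band: SpectralBand, optics: EffectiveOptics) -> float:
    """Attenuation rescaling mu_i/mu_av = (beta_i omega_i)/(beta_av omega_av).

    Follows from mu = 2 k beta with k proportional to the photon energy.
    """
    return (band.beta * band.omega) / (optics.beta_av * optics.omega_av)


def band_fields(
    a: np.ndarray, band: SpectralBand, optics: EffectiveOptics
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band exit intensity and phase for absorption variable ``a``.

    ``a_i = a * (beta_i omega_i)/(beta_av omega_av)`` rescales the effective
    absorption to band ``i``; then ``I_i = f_i exp(-a_i)`` (fractional
    Beer-Lambert) and ``phi_i = -(delta_i/beta_i) a_i / 2``.  For a single
    band at the effective energy this reduces to ``(exp(-a),
    phase_from_absorption(a))``.
    """
    a = np.asarray(a, dtype=float)
    a_i = a * band_scale(band, optics)
    I_i = band.f * np.exp(-a_i)
    phi_i = -(band.delta / band.beta) * a_i / 2.0
    return I_i, phi_i


def confusion_width(
    source_fwhm: float, source_sample_distance: float, L: float
) -> float:
    """Geometric penumbra of the source at the detector, sample-plane scale.

    ``source_fwhm * L / source_sample_distance``; with a 140 um source at
    145 m and 30 m of propagation this is ~29 um, the classic figure limiting
    pre-upgrade phase-contrast setups.
    """
    if source_sample_distance <= 0 or L <= 0:
        raise ValueError("distances must be positive")
    if source_fwhm < 0:
        raise ValueError("source FWHM must be non-negative")
    return source_fwhm * L / source_sample_distance


def load_spectrum(path) -> BeamSpectrum:
    """Read a two-column (energy_keV, weight) whitespace/CSV text file."""
    try:
        arr = np.loadtxt(path, comments="#")
    except ValueError:
        arr = np.loadtxt(path, delimiter=",", comments="#")
    arr = np.atleast_2d(arr)
    return BeamSpectrum(arr[:, 0], arr[:, 1])
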