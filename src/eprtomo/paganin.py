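"""Linearized (TIE) forward model and single-distance Paganin retrieval.

The transport-of-intensity equation relates the longitudinal intensity
derivative to the transverse intensity/phase derivatives,

    I(x, y, L) = I(x, y, 0) - (L/k) div( I grad phi ),

and with the homogeneous-object assumption phi = (delta/beta) ln(I/I0) / 2
the right-hand side collapses to a Laplacian of I, which a single Fourier
filter inverts (the Paganin filter).  All discrete operators here are
centered second-order stencils in conservative (flux) form, so total
intensity is conserved under both boundary conditions, and the Fourier
filter uses the discrete-Laplacian symbol 2 - 2 cos(q h) so that retrieval
is a grid-exact inverse of the matched forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import EffectiveOptics, Geometry, SpectralBand, band_fields

__all__ = [
    "UnsharpParams",
    "tie_forward",
    "paganin_retrieve",
    "linear_forward_poly",
    "unsharp_mask",
]


@dataclass(frozen=True)
class UnsharpParams:
    """High-boost unsharp mask settings (HiP-CT protocol defaults)."""

    sigma: float = 1.2  # pixels
    coeff: float = 4.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("unsharp sigma must be positive")
        if self.coeff < 0:
            raise ValueError("unsharp coefficient must be non-negative")


def _pad1(arr: np.ndarray, bc: str) -> np.ndarray:
    mode = {"replicate": "edge", "periodic": "wrap"}[bc]
    return np.pad(arr, 1, mode=mode)


def _face_intensity(Ia: np.ndarray, Ib: np.ndarray, face: str) -> np.ndarray:
    """Intensity at the staggered face between two neighbouring pixels.

    'arithmetic' keeps the operator strictly linear in I; 'logmean' (the
    logarithmic mean) makes div(I grad phi) with phi = c ln I collapse
    exactly to c * Laplacian(I) on the grid, which is what the Paganin
    filter inverts.
    """
    if face == "arithmetic":
        return 0.5 * (Ia + Ib)
    if face == "logmean":
        num = Ib - Ia
        den = np.log(Ib) - np.log(Ia)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        return np.where(np.abs(den) < 1e-12, Ia, out)
    raise ValueError(f"unknown face intensity rule {face!r}")


def tie_divergence(
    I0: np.ndarray, phi: np.ndarray, bc: str = "replicate", face: str = "arithmetic"
) -> np.ndarray:
    """div( I grad phi ) in per-pixel^2 units, conservative staggered stencil."""
    Ip = _pad1(np.asarray(I0, dtype=float), bc)
    pp = _pad1(np.asarray(phi, dtype=float), bc)
    # fluxes across vertical faces (axis 1) and horizontal faces (axis 0)
    fx = _face_intensity(Ip[1:-1, :-1], Ip[1:-1, 1:], face) * (
        pp[1:-1, 1:] - pp[1:-1, :-1]
    )
    fy = _face_intensity(Ip[:-1, 1:-1], Ip[1:, 1:-1], face) * (
        pp[1:, 1:-1] - pp[:-1, 1:-1]
    )
    return (fx[:, 1:] - fx[:, :-1]) + (fy[1:, :] - fy[:-1, :])


def _wide_divergence(I0: np.ndarray, phi: np.ndarray, bc: str) -> np.ndarray:
    """div( I grad phi ) with wide centered differences ((f[i+1]-f[i-1])/2).

    This is the stencil the eikonal model's shift field uses, so it is the
    right linear model to compare that model against.
    """
    if bc == "replicate":
        Ip = np.pad(I0, 2, mode="edge")
        pp = np.pad(phi, 2, mode="edge")
        out = _wide_divergence(Ip, pp, "periodic")
        return out[2:-2, 2:-2]
    dx = lambda u: 0.5 * (np.roll(u, -1, axis=1) - np.roll(u, 1, axis=1))
    dy = lambda u: 0.5 * (np.roll(u, -1, axis=0) - np.roll(u, 1, axis=0))
    return dx(I0 * dx(phi)) + dy(I0 * dy(phi))


def tie_forward(
    I0: np.ndarray,
    phi: np.ndarray,
    geometry: Geometry,
    k: float,
    bc: str = "replicate",
    face: str = "arithmetic",
    stencil: str = "staggered",
) -> np.ndarray:
    """Propagate exit intensity I0 with phase phi over distance L (linearized).

    Output may go negative for strong phase — the known failure mode of the
    linearization — and is deliberately not clipped.  ``stencil='staggered'``
    is the conservative flux form (see :func:`tie_divergence`);
    ``stencil='wide'`` uses plain centered differences for both derivative
    applications, matching the eikonal model's first-order term.
    """
    I0 = np.asarray(I0, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if I0.shape != phi.shape:
        raise ValueError(f"shape mismatch: I0 {I0.shape} vs phi {phi.shape}")
    coef = geometry.L / (k * geometry.pixel**2)
    if stencil == "staggered":
        div = tie_divergence(I0, phi, bc=bc, face=face)
    elif stencil == "wide":
        div = _wide_divergence(I0, phi, bc)
    else:
        raise ValueError(f"unknown stencil {stencil!r}")
    return I0 - coef * div


def _laplacian_symbol(shape: tuple[int, int]) -> np.ndarray:
    """Eigenvalues (>= 0) of minus the 5-point Laplacian under periodic BC."""
    qy = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(shape[0]))
    qx = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(shape[1]))
    return qy[:, None] + qx[None, :]


def paganin_retrieve(
    I_L: np.ndarray,
    geometry: Geometry,
    delta_beta: float,
    k: float,
    I0: float = 1.0,
    bc: str = "replicate",
    pad: int | None = None,
) -> np.ndarray:
    """Closed-form single-distance retrieval of the effective absorption.

    a = -ln( F^-1[ F[I_L/I0] / (1 + (L db / (2 k h^2)) * Lambda(q)) ] )

    with Lambda the discrete-Laplacian symbol (2-2cos per axis).  With
    ``bc='periodic'`` this inverts ``tie_forward(exp(-a), -db*a/2, ...,
    bc='periodic', face='logmean')`` to machine precision.  ``bc='replicate'``
    edge-pads before the FFT (default pad: half the smaller image dimension,
    capped at 256 pixels).
    """
    if delta_beta < 0:
        raise ValueError("delta/beta ratio must be non-negative")
    M = np.asarray(I_L, dtype=float) / I0
    if bc == "replicate":
        if pad is None:
            pad = min(min(M.shape) // 2, 256)
        Mp = np.pad(M, pad, mode="edge")
    elif bc == "periodic":
        pad = 0
        Mp = M
    else:
        raise ValueError(f"unknown boundary condition {bc!r}")
    coef = geometry.L * delta_beta / (2.0 * k * geometry.pixel**2)
    filt = np.fft.ifft2(np.fft.fft2(Mp) / (1.0 + coef * _laplacian_symbol(Mp.shape))).real
    if pad:
        filt = filt[pad:-pad, pad:-pad]
    n_bad = int(np.count_nonzero(filt <= 0))
    if n_bad:
        raise ValueError(
            f"filtered intensity non-positive at {n_bad} pixel(s); "
            "cannot take the logarithm"
        )
    return -np.log(filt)


def linear_forward_poly(
    a: np.ndarray,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
    bc: str = "replicate",
    face: str = "arithmetic",
) -> np.ndarray:
    """Polychromatic linearized forward: sum of per-band TIE propagations.

    Drop-in replacement for the eikonal forward model inside the solver;
    realizes the 'polychromatic Paganin' comparison model.
    """
    out = np.zeros_like(np.asarray(a, dtype=float))
    for band in bands:
        I_i, phi_i = band_fields(a, band, optics)
        out += tie_forward(I_i, phi_i, geometry, band.k, bc=bc, face=face)
    return out


def _lap_periodic(u: np.ndarray) -> np.ndarray:
    return (
        np.roll(u, 1, axis=0)
        + np.roll(u, -1, axis=0)
        + np.roll(u, 1, axis=1)
        + np.roll(u, -1, axis=1)
        - 4.0 * u
    )


def homogeneous_coefficient(band: SpectralBand, geometry: Geometry) -> float:
    """C_i = L delta_i / (2 k_i beta_i h^2), the per-band Paganin filter scale."""
    return geometry.L * band.delta / (2.0 * band.k * band.beta * geometry.pixel**2)


def homogeneous_forward(
    a: np.ndarray,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
) -> np.ndarray:
    """Linearized forward in homogeneous (diagonal) form, periodic BC.

    Per band ``I_i - C_i Lap(I_i)``; identical on the grid to
    :func:`linear_forward_poly` with logarithmic-mean faces, because
    div(I grad(c ln I)) = c Lap(I) holds exactly for that flux rule.  This
    is the model the Paganin filter inverts, and the solver's
    ``forward_kind='linearized'`` model.
    """
    a = np.asarray(a, dtype=float)
    out = np.zeros_like(a)
    for band in bands:
        I_i, _ = band_fields(a, band, optics)
        out += I_i - homogeneous_coefficient(band, geometry) * _lap_periodic(I_i)
    return out


def homogeneous_misfit_gradient(
    a: np.ndarray,
    data: np.ndarray,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
    forward: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Exact L2 misfit gradient of :func:`homogeneous_forward`.

    The per-band map a -> I_i - C_i Lap(I_i) has Jacobian
    (1 - C_i Lap) diag(dI_i/da); 1 - C_i Lap is symmetric under periodic BC.
    """
    from .optics import band_scale  # local import to avoid cycle at module load

    a = np.asarray(a, dtype=float)
    if forward is None:
        forward = homogeneous_forward(a, bands, geometry, optics)
    residual = forward - np.asarray(data, dtype=float)
    misfit = float(np.sum(residual**2))
    grad = np.zeros_like(a)
    for band in bands:
        I_i, _ = band_fields(a, band, optics)
        C = homogeneous_coefficient(band, geometry)
        u = residual - C * _lap_periodic(residual)
        grad += -band_scale(band, optics) * I_i * u
    return misfit, 2.0 * grad


def unsharp_mask(
    image: np.ndarray, params: UnsharpParams, bc: str = "replicate"
) -> np.ndarray:
    """Additive high-boost filter: out = image + coeff * (image - G_sigma * image)."""
    mode = {"replicate": "nearest", "periodic": "wrap"}[bc]
    blurred = gaussian_filter(np.asarray(image, dtype=float), params.sigma, mode=mode)
    return image + params.coeff * (image - blurred)
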