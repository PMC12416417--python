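"""Nonlinear eikonal forward model: phase-gradient shifts and ray splatting.

In the near-field, short-coherence regime the Huygens-Fresnel integral
reduces to geometric transport: each wavefront pixel's intensity lands on
the detector displaced by s = (L/k) grad(phi).  The splat distributes a
pixel's intensity over the detector cells overlapped by the quadrilateral
spanned by its four ray-traced corners, so rays may cross (caustic folding)
and intensity may appear outside a feature's geometric shadow — exactly the
behaviour the linearized TIE model cannot represent.  Interference between
distinct ray paths is discarded (incoherent near-field limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._splat import splat_gather, splat_scatter
from .optics import EffectiveOptics, Geometry, SpectralBand, band_fields, band_scale

__all__ = [
    "ShiftField",
    "SplatAccumulator",
    "shift_field",
    "eikonal_splat",
    "eikonal_splat_adjoint",
    "epr_forward_model",
    "epr_forward_jvp",
    "misfit_gradient",
]


@dataclass(frozen=True)
class ShiftField:
    """Per-pixel transverse detector displacement in pixel units."""

    s_x: np.ndarray
    s_y: np.ndarray

    def __post_init__(self):
        sx = np.asarray(self.s_x, dtype=float)
        sy = np.asarray(self.s_y, dtype=float)
        if sx.shape != sy.shape:
            raise ValueError("s_x and s_y must share a shape")
        object.__setattr__(self, "s_x", sx)
        object.__setattr__(self, "s_y", sy)


@dataclass
class SplatAccumulator:
    """Detector accumulation grid plus the intensity that left it."""

    detector: np.ndarray
    escaped: float


def shift_coefficient(geometry: Geometry, k: float) -> float:
    """Pixels of transverse shift per unit phase gradient (rad/pixel)."""
    return geometry.L / (k * geometry.pixel**2)


def shift_field(phi: np.ndarray, geometry: Geometry, k: float) -> ShiftField:
    """Ray shifts s = (L/k) grad(phi) in pixel units, centered differences."""
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase map must be finite")
    # per-pixel phase derivatives; degenerate (single-row/col) axes get 0
    gy = np.gradient(phi, axis=0) if phi.shape[0] > 1 else np.zeros_like(phi)
    gx = np.gradient(phi, axis=1) if phi.shape[1] > 1 else np.zeros_like(phi)
    c = shift_coefficient(geometry, k)
    return ShiftField(s_x=c * gx, s_y=c * gy)


def _corner_interp(field: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a pixel-centered field to pixel corners.

    (H, W) -> (H+1, W+1); edge corners replicate the boundary pixels.
    """
    p = np.pad(field, 1, mode="edge")
    return 0.25 * (p[:-1, :-1] + p[:-1, 1:] + p[1:, :-1] + p[1:, 1:])


def _corner_maps(shifts: ShiftField) -> tuple[np.ndarray, np.ndarray]:
    H, W = shifts.s_x.shape
    jj = np.arange(W + 1) - 0.5
    ii = np.arange(H + 1) - 0.5
    cx = jj[None, :] + _corner_interp(shifts.s_x)
    cy = ii[:, None] + _corner_interp(shifts.s_y)
    return cx, cy


def eikonal_splat(
    I0: np.ndarray, shifts: ShiftField, out_shape: tuple[int, int] | None = None
) -> SplatAccumulator:
    """Transport intensity along ray-traced pixel quadrilaterals.

    Total intensity (detector + escaped) is conserved to rounding; overlapping
    quadrilaterals add, so folds (caustics) brighten rather than break.
    """
    I0 = np.asarray(I0, dtype=float)
    if I0.shape != shifts.s_x.shape:
        raise ValueError("intensity and shift field shapes must match")
    if not (np.all(np.isfinite(shifts.s_x)) and np.all(np.isfinite(shifts.s_y))):
        raise ValueError("shift field contains non-finite values")
    cx, cy = _corner_maps(shifts)
    out = np.zeros(out_shape if out_shape is not None else I0.shape)
    escaped = splat_scatter(I0, cx, cy, out)
    return SplatAccumulator(detector=out, escaped=float(escaped))


def eikonal_splat_adjoint(residual: np.ndarray, shifts: ShiftField) -> np.ndarray:
    """Exact transpose of the splat at fixed shifts (gather along rays)."""
    residual = np.asarray(residual, dtype=float)
    cx, cy = _corner_maps(shifts)
    out = np.zeros(shifts.s_x.shape)
    splat_gather(residual, cx, cy, out)
    return out


def caustic_mask(
    shifts: ShiftField, jacobian_min: float = 0.5, jacobian_max: float = 2.0
) -> np.ndarray:
    """Flag pixels where the ray map folds or compresses strongly.

    The transport Jacobian J = det(I + ds/dx) measures local beam
    compression; J <= 0 is a fold (caustic).  Returns a boolean mask of
    pixels with J outside [jacobian_min, jacobian_max].
    """
    gxx = _dx(shifts.s_x)
    gxy = _dy(shifts.s_x)
    gyx = _dx(shifts.s_y)
    gyy = _dy(shifts.s_y)
    J = (1.0 + gxx) * (1.0 + gyy) - gxy * gyx
    return (J < jacobian_min) | (J > jacobian_max)


def epr_forward_model(
    a: np.ndarray,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
    return_escaped: bool = False,
):
    """Detector intensity as a functional of the effective absorption.

    Per band: exit fields from :func:`band_fields`, shifts from the band's
    own wavelength, then a conservative splat; bands add incoherently.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("absorption map must be finite")
    total = np.zeros_like(a)
    escaped = 0.0
    for band in bands:
        I_i, phi_i = band_fields(a, band, optics)
        acc = eikonal_splat(I_i, shift_field(phi_i, geometry, band.k))
        total += acc.detector
        escaped += acc.escaped
    if return_escaped:
        return total, escaped
    return total


# ---------------------------------------------------------------------------
# Linearization (frozen-shift Gauss-Newton) and its exact transpose.
#
# The splat is differentiated only through its intensity argument (exact
# transpose available); the dependence through the shifts is linearized with
# the transport-of-divergence approximation  dF[ds] ~= S[-div(I ds)], whose
# small-shift limit is the TIE.  Stencils below are centered periodic so
# grad^T = -div holds exactly and the vjp is the exact transpose of the jvp.
# ---------------------------------------------------------------------------


def _dx(u):
    return 0.5 * (np.roll(u, -1, axis=1) - np.roll(u, 1, axis=1))


def _dy(u):
    return 0.5 * (np.roll(u, -1, axis=0) - np.roll(u, 1, axis=0))


def _div(fx, fy):
    return _dx(fx) + _dy(fy)


def _band_linearization(a, band, optics, geometry):
    I_i, phi_i = band_fields(a, band, optics)
    sc = band_scale(band, optics)
    shifts = shift_field(phi_i, geometry, band.k)
    c = shift_coefficient(geometry, band.k)
    dphi_da = -(band.delta / band.beta) * sc / 2.0
    return I_i, shifts, sc, c, dphi_da


def epr_forward_jvp(
    a: np.ndarray,
    da: np.ndarray,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
) -> np.ndarray:
    """Directional derivative of the forward model at ``a`` along ``da``."""
    a = np.asarray(a, dtype=float)
    da = np.asarray(da, dtype=float)
    out = np.zeros_like(a)
    for band in bands:
        I_i, shifts, sc, c, dphi_da = _band_linearization(a, band, optics, geometry)
        dI = -sc * I_i * da
        dphi = dphi_da * da
        dsx = c * _dx(dphi)
        dsy = c * _dy(dphi)
        payload = dI - _div(I_i * dsx, I_i * dsy)
        out += eikonal_splat(payload, shifts).detector
    return out


def epr_forward_vjp(
    a: np.ndarray,
    residual: np.ndarray,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
) -> np.ndarray:
    """Exact transpose of :func:`epr_forward_jvp` applied to ``residual``."""
    a = np.asarray(a, dtype=float)
    out = np.zeros_like(a)
    for band in bands:
        I_i, shifts, sc, c, dphi_da = _band_linearization(a, band, optics, geometry)
        u = eikonal_splat_adjoint(residual, shifts)
        # attenuation chain
        out += -sc * I_i * u
        # refraction chain: adjoint of ds -> S[-div(I ds)] then of dphi -> c grad
        gx = I_i * _dx(u)
        gy = I_i * _dy(u)
        out += dphi_da * (-c * _div(gx, gy))
    return out


def misfit_gradient(
    a: np.ndarray,
    data: np.ndarray,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
    forward: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """L2 misfit and its Gauss-Newton gradient with respect to ``a``.

    misfit = sum((F(a) - data)^2); the gradient is 2 * dF^T residual with dF
    the frozen-shift linearization above, validated against directional
    finite differences of the linearized objective.
    """
    a = np.asarray(a, dtype=float)
    data = np.asarray(data, dtype=float)
    if a.shape != data.shape:
        raise ValueError("absorption and data shapes must match")
    if forward is None:
        forward = epr_forward_model(a, bands, geometry, optics)
    residual = forward - data
    misfit = float(np.sum(residual**2))
    grad = 2.0 * epr_forward_vjp(a, residual, bands, geometry, optics)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite gradient")
    return misfit, grad
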