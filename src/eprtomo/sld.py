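"""Scintillator point-spread-function model, fitting, and deconvolution.

Light generated in the scintillator partly stays trapped by total internal
reflection and diffuses before escaping, adding a long-range halo around
bright regions.  The PSF ansatz is

    p(r) = (1 - f) delta(r) + f g exp(-alpha r) / r     (r >= 1 pixel)

with ``f`` the fraction of collected light in the tail, ``alpha`` the
inverse damping length, and ``g`` fixed by normalizing the kernel sum to 1.
The 1/r factor is the 2-D geometric spread, the exponential the escape/
absorption damping.  Parameters are fitted from a slit-collimated spot's
halo; the kernel then deconvolves raw radiographs (and their flats) before
flat-field normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["PSFModel", "SpotImage", "build_psf", "fit_psf", "convolve", "deconvolve"]


def default_support(alpha: float, coverage: float = 0.999) -> int:
    """Radius (pixels) at which the cumulative tail mass reaches ``coverage``.

    Uses the continuum estimate: tail mass beyond R falls off as
    exp(-alpha (R - 1)).
    """
    return max(2, int(np.ceil(1.0 - np.log(1.0 - coverage) / alpha)))


def _tail_grid(alpha: float, support: int) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized tail exp(-alpha r)/r on a (2R+1)^2 grid, zero at r = 0."""
    idx = np.arange(-support, support + 1)
    r = np.hypot(idx[:, None], idx[None, :])
    with np.errstate(divide="ignore"):
        tail = np.exp(-alpha * r) / r
    tail[support, support] = 0.0
    tail[r > support] = 0.0
    return tail, r


def tail_normalization(alpha: float, support: int) -> float:
    """g such that g * sum_{0<r<=support} exp(-alpha r)/r = 1."""
    tail, _ = _tail_grid(alpha, support)
    return 1.0 / float(tail.sum())


@dataclass(frozen=True)
class PSFModel:
    """Discretized scintillator PSF kernel and its parameters."""

    f: float
    alpha: float
    g: float
    support: int
    kernel: np.ndarray

    @property
    def tail_mass(self) -> float:
        """Fraction of the kernel mass off the central pixel."""
        c = self.support
        return float(self.kernel.sum() - self.kernel[c, c])


@dataclass(frozen=True)
class SpotImage:
    """Slit-collimated bright spot and its halo."""

    pixels: np.ndarray
    spot_mask: np.ndarray

    def __post_init__(self):
        if not np.any(self.spot_mask):
            raise ValueError("spot mask is empty")
        if self.pixels.shape != self.spot_mask.shape:
            raise ValueError("pixels and mask shapes must match")


def build_psf(
    f: float,
    alpha: float,
    support: int | None = None,
    truncation_tol: float = 1e-3,
) -> PSFModel:
    """Build the normalized PSF kernel on a (2*support+1)^2 grid.

    With ``f = 0`` the kernel is the discrete identity.  Raises if the
    requested support truncates more than ``truncation_tol`` of the tail
    mass (continuum estimate exp(-alpha (support - 1))).
    """
    if not (0.0 <= f < 1.0):
        raise ValueError(f"tail fraction must be in [0, 1), got {f}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if support is None:
        support = default_support(alpha, coverage=1.0 - min(truncation_tol, 1e-3))
    if support < 1:
        raise ValueError("support must be >= 1 pixel")
    truncated = np.exp(-alpha * (support - 1.0))
    if f > 0 and truncated > truncation_tol:
        raise ValueError(
            f"support={support} truncates ~{truncated:.2e} of the tail mass "
            f"(> {truncation_tol:g}); use support >= "
            f"{default_support(alpha, 1.0 - truncation_tol)}"
        )
    tail, _ = _tail_grid(alpha, support)
    s = float(tail.sum())
    g = 1.0 / s if s > 0 else 0.0
    kernel = f * g * tail
    kernel[support, support] = 1.0 - f
    return PSFModel(f=f, alpha=alpha, g=g, support=support, kernel=kernel)


def _radial_profile(
    image: np.ndarray, center: tuple[float, float], r_min: float, r_max: float
) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.indices(image.shape)
    r = np.hypot(yy - center[0], xx - center[1])
    sel = (r >= r_min) & (r <= r_max)
    bins = np.round(r[sel]).astype(int)
    counts = np.bincount(bins)
    sums = np.bincount(bins, weights=image[sel])
    rsums = np.bincount(bins, weights=r[sel])
    valid = counts > 0
    # label each bin by its pixels' mean radius: partial edge bins would
    # otherwise be mislabeled by up to half a pixel, a several-percent model
    # error where the halo is steepest
    radii = rsums[valid] / counts[valid]
    return radii, sums[valid] / counts[valid]


def fit_psf(
    spot: SpotImage,
    method: str = "radial",
    margin: float = 3.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Estimate (f, alpha) from a spot image's halo.

    Radially averages the halo about the spot centroid, fits
    ``log(r * halo) = log(f g T) - alpha r`` by least squares, then jointly
    refines (f, alpha) against the full tail model.  Returns
    ``((f, alpha), (stderr_f, stderr_alpha))``.  ``method='image'`` refines
    against every halo pixel instead of the radial profile.
    """
    img = np.asarray(spot.pixels, dtype=float)
    mask = np.asarray(spot.spot_mask, dtype=bool)
    total_flux = float(img.sum())
    halo_flux = float(img[~mask].sum())
    if halo_flux <= 1e-9 * total_flux:
        # no detectable diffused light: ideal scintillator, infinite damping
        return (0.0, float("inf")), (0.0, 0.0)
    if int(np.count_nonzero(img[~mask] > 0)) < 100:
        raise ValueError("halo must contain at least 100 pixels with positive signal")
    w = np.clip(img, 0, None) * mask
    tot_w = w.sum()
    cy = float((np.indices(img.shape)[0] * w).sum() / tot_w)
    cx = float((np.indices(img.shape)[1] * w).sum() / tot_w)
    # radius of the direct spot, padded by a safety margin
    yy, xx = np.nonzero(mask)
    r_spot = float(np.hypot(yy - cy, xx - cx).max())
    r_min = r_spot + margin
    r_max = min(cy, cx, img.shape[0] - 1 - cy, img.shape[1] - 1 - cx)
    if r_max <= r_min + 5:
        raise ValueError("halo region too small around the spot")
    radii, prof = _radial_profile(img, (cy, cx), r_min, r_max)
    # the measured halo ends where the (finite-support) tail runs out; keep
    # the contiguous positive head of the profile
    pos = prof > 0
    if not pos.all():
        cut = int(np.argmin(pos))
        radii, prof = radii[:cut], prof[:cut]
    if radii.size < 20:
        raise ValueError("radial halo profile has too few positive bins")

    # stage 1: log-linear fit of r*halo(r)
    y = np.log(radii * prof)
    A = np.vstack([np.ones_like(radii), -radii]).T
    (b0, alpha0), *_ = np.linalg.lstsq(A, y, rcond=None)
    if alpha0 <= 0:
        raise ValueError("halo profile is not decaying; cannot fit damping length")
    support = default_support(alpha0, coverage=0.99999)
    g0 = tail_normalization(alpha0, support)
    f0 = float(np.clip(np.exp(b0) / (g0 * total_flux), 1e-9, 0.95))

    # stage 2: joint nonlinear refinement against the full model prediction:
    # the halo is the measured direct spot (scaled back by 1/(1-f)) convolved
    # with the tail, evaluated at sample points of each radial ring (or at
    # every halo pixel for method='image')
    spot_y, spot_x = np.nonzero(mask)
    spot_w = img[mask]
    if method == "radial":
        n_samp = 128
        phis = np.linspace(0.0, 2.0 * np.pi, n_samp, endpoint=False)
        py = cy + radii[:, None] * np.sin(phis)[None, :]
        px = cx + radii[:, None] * np.cos(phis)[None, :]
        # distances (n_bins, n_samp, n_spot)
        dist = np.hypot(
            py[..., None] - spot_y[None, None, :],
            px[..., None] - spot_x[None, None, :],
        )
        h_fit = prof

        def geom(alpha_):
            return np.mean(
                np.sum(spot_w * np.exp(-alpha_ * dist) / dist, axis=-1), axis=-1
            )

    elif method == "image":
        yy, xx = np.indices(img.shape)
        rr = np.hypot(yy - cy, xx - cx)
        sel = (rr >= r_min) & (rr <= r_max)
        hy, hx = np.nonzero(sel)
        if hy.size > 20000:
            pick = np.linspace(0, hy.size - 1, 20000).astype(int)
            hy, hx = hy[pick], hx[pick]
        dist = np.hypot(
            hy[:, None] - spot_y[None, :], hx[:, None] - spot_x[None, :]
        )
        h_fit = img[hy, hx]

        def geom(alpha_):
            return np.sum(spot_w * np.exp(-alpha_ * dist) / dist, axis=-1)

    else:
        raise ValueError(f"unknown fit method {method!r}")

    def model(theta):
        f_, alpha_ = theta
        g_ = tail_normalization(alpha_, support)
        return (f_ / (1.0 - f_)) * g_ * geom(alpha_)

    # distances among spot pixels, for the self-halo correction below
    dspot = np.hypot(
        spot_y[:, None] - spot_y[None, :], spot_x[:, None] - spot_x[None, :]
    )
    np.fill_diagonal(dspot, np.inf)

    spot_w0 = spot_w.copy()
    res = None
    for _ in range(2):  # refit once with self-halo-corrected spot weights
        res = least_squares(
            lambda th: model(th) - h_fit,
            x0=[f0, alpha0],
            bounds=([0.0, alpha0 * 0.05], [0.999, alpha0 * 20.0]),
            xtol=1e-12,
            ftol=1e-12,
        )
        f_hat, alpha_hat = res.x
        g_hat = tail_normalization(alpha_hat, support)
        self_halo = (f_hat / (1.0 - f_hat)) * g_hat * np.sum(
            spot_w0 * np.exp(-alpha_hat * dspot) / dspot, axis=-1
        )
        spot_w = np.clip(spot_w0 - self_halo, 0.0, None)
    f_hat, alpha_hat = res.x
    # asymptotic standard errors from the Jacobian at the solution
    dof = max(h_fit.size - 2, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        err = tuple(np.sqrt(np.clip(np.diag(cov), 0, None)))
    except np.linalg.LinAlgError:
        err = (np.nan, np.nan)
    return (float(f_hat), float(alpha_hat)), (float(err[0]), float(err[1]))


def _padded_otf(psf: PSFModel, shape: tuple[int, int]) -> np.ndarray:
    big = np.zeros(shape)
    k = psf.kernel
    n = k.shape[0]
    big[:n, :n] = k
    big = np.roll(big, (-psf.support, -psf.support), axis=(0, 1))
    return np.fft.fft2(big)


def convolve(image: np.ndarray, psf: PSFModel) -> np.ndarray:
    """Blur an image with the PSF (edge-replicate padding by the support)."""
    p = psf.support
    padded = np.pad(np.asarray(image, dtype=float), p, mode="edge")
    out = np.fft.ifft2(np.fft.fft2(padded) * _padded_otf(psf, padded.shape)).real
    return out[p:-p, p:-p]


def deconvolve(raw: np.ndarray, psf: PSFModel) -> np.ndarray:
    """Invert the PSF convolution by Fourier division.

    The transfer function's DC gain is exactly 1 (flux preserved) and its
    modulus stays well away from zero for tail fractions f < 1/2, so no
    regularization is needed.
    """
    if psf.f >= 1.0:
        raise ValueError("tail fraction f >= 1: PSF is not invertible")
    p = psf.support
    padded = np.pad(np.asarray(raw, dtype=float), p, mode="edge")
    otf = _padded_otf(psf, padded.shape)
    if np.min(np.abs(otf)) < 1e-6:
        raise ValueError("PSF transfer function too close to zero; cannot deconvolve")
    out = np.fft.ifft2(np.fft.fft2(padded) / otf).real
    return out[p:-p, p:-p]
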