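"""Hierarchically preconditioned nonlinear conjugate-gradient inversion.

The forward model (eikonal splat or linearized/homogeneous) is inverted per
projection by minimizing the L2 misfit with Polak-Ribiere nonlinear CG and
an Armijo backtracking line search.  Two preconditioners tame the problem's
high condition number (high spatial frequencies converge much faster than
low ones and overfit unmodellable data around sharp edges):

* a spectral preconditioner, the inverse Paganin filter symbol
  (1 + C Lambda(q))^-p applied to the gradient — the Gauss-Newton Hessian
  of the misfit is ~ diag(I^2) (1 + C q^2)^2, so this equalizes per-mode
  convergence rates and makes the first step land near the closed-form
  Paganin solution;
* the coarse-to-fine dyadic pyramid: the coarsest level, where phase
  effects are negligible, is initialized with the trivial pure-absorption
  logarithm, and each finer level starts from the upsampled coarser
  solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import zoom

from .eikonal import epr_forward_model, misfit_gradient
from .optics import EffectiveOptics, Geometry, SpectralBand
from .paganin import _laplacian_symbol, homogeneous_forward, homogeneous_misfit_gradient

__all__ = ["SolverConfig", "nonlinear_cg", "hierarchical_solve"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Inversion settings; defaults follow the production recipe
    (7 scale levels, ~30 CG iterations per level, 5 spectral points)."""

    n_levels: int = 7
    n_cg: int = 30
    forward_kind: str = "eikonal"  # 'eikonal' | 'linearized'
    n_bands: int = 5
    tol: float = 1e-10  # relative misfit stagnation tolerance
    armijo_c1: float = 1e-4
    max_backtracks: int = 25
    precond: str = "paganin"  # 'paganin' | 'none'
    precond_power: float = 3.0

    def __post_init__(self):
        if self.n_levels < 1 or self.n_cg < 1:
            raise ValueError("n_levels and n_cg must be >= 1")
        if self.forward_kind not in ("eikonal", "linearized"):
            raise ValueError(f"unknown forward_kind {self.forward_kind!r}")
        if self.precond not in ("paganin", "none"):
            raise ValueError(f"unknown preconditioner {self.precond!r}")


def _evaluators(config: SolverConfig):
    if config.forward_kind == "eikonal":
        return epr_forward_model, misfit_gradient
    return homogeneous_forward, homogeneous_misfit_gradient


def _preconditioner(
    config: SolverConfig,
    shape: tuple[int, int],
    geometry: Geometry,
    optics: EffectiveOptics,
):
    """Return a symmetric positive-definite gradient filter, or identity."""
    if config.precond == "none":
        return lambda g: g
    C = geometry.L * optics.ratio / (2.0 * optics.k * geometry.pixel**2)
    M = 1.0 / (1.0 + C * _laplacian_symbol(shape)) ** config.precond_power
    return lambda g: np.fft.ifft2(np.fft.fft2(g) * M).real


def nonlinear_cg(
    data: np.ndarray,
    a0: np.ndarray,
    config: SolverConfig,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
) -> np.ndarray:
    """Preconditioned Polak-Ribiere NCG; returns the best (lowest-misfit) iterate.

    The misfit is non-increasing across accepted steps; a failed line search
    falls back to a (preconditioned) steepest-descent step before giving up.
    """
    forward_fn, grad_fn = _evaluators(config)
    data = np.asarray(data, dtype=float)
    a = np.asarray(a0, dtype=float).copy()
    if a.shape != data.shape:
        raise ValueError("a0 and data shapes must match")
    applyM = _preconditioner(config, data.shape, geometry, optics)

    F = forward_fn(a, bands, geometry, optics)
    J, g = grad_fn(a, data, bands, geometry, optics, forward=F)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient at the starting point")
    best_J, best_a = J, a.copy()
    if float(np.dot(g.ravel(), g.ravel())) == 0.0:
        return best_a
    Mg = applyM(g)
    gMg = float(np.sum(g * Mg))
    d = -Mg
    s_prev = y_prev = None
    step = None

    for it in range(config.n_cg):
        gd = float(np.sum(g * d))
        if gd >= 0.0:  # not a descent direction: restart
            d = -Mg
            gd = -gMg
        if s_prev is not None:
            sy = float(np.sum(s_prev * y_prev))
            step = float(np.sum(s_prev * s_prev)) / sy if sy > 0 else None
        if step is None:
            step = J / max(-gd, 1e-300)  # scale-aware first guess
        accepted = False
        t = step
        for attempt in range(2):  # CG direction, then steepest-descent fallback
            tt = t
            for _ in range(config.max_backtracks):
                a_try = a + tt * d
                F_try = forward_fn(a_try, bands, geometry, optics)
                J_try = float(np.sum((F_try - data) ** 2))
                if J_try <= J + config.armijo_c1 * tt * gd:
                    accepted = True
                    break
                tt *= 0.5
            if accepted:
                break
            log.debug("line search failed at iter %d; steepest-descent fallback", it)
            d = -Mg
            gd = -gMg
            t = J / max(-gd, 1e-300)
        if not accepted:
            log.debug("no acceptable step at iter %d; stopping", it)
            break

        a_new = a + tt * d
        J_new, g_new = grad_fn(a_new, data, bands, geometry, optics, forward=F_try)
        if not np.all(np.isfinite(g_new)):
            raise FloatingPointError("non-finite gradient during iteration")
        Mg_new = applyM(g_new)
        gMg_new = float(np.sum(g_new * Mg_new))
        # Polak-Ribiere+ in the preconditioned metric (restart through max(0,.))
        beta = (
            max(0.0, float(np.sum(g_new * (Mg_new - Mg))) / gMg) if gMg > 0 else 0.0
        )
        s_prev, y_prev = a_new - a, g_new - g
        d = -Mg_new + beta * d
        rel_drop = (J - J_new) / J if J > 0 else 0.0
        a, J, g, Mg, gMg = a_new, J_new, g_new, Mg_new, gMg_new
        if J < best_J:
            best_J, best_a = J, a.copy()
        log.debug("cg iter %d: misfit %.6e (step %.3e)", it, J, tt)
        if rel_drop < config.tol:
            break
    return best_a


def _box_down(img: np.ndarray) -> np.ndarray:
    """2x2 box-mean downsampling."""
    H, W = img.shape
    return img.reshape(H // 2, 2, W // 2, 2).mean(axis=(1, 3))


def _bilinear_up(img: np.ndarray) -> np.ndarray:
    """x2 bilinear upsampling, adjoint-consistent with the box mean."""
    return zoom(img, 2, order=1, mode="nearest", grid_mode=True)


def hierarchical_solve(
    data: np.ndarray,
    config: SolverConfig,
    bands: list[SpectralBand],
    geometry: Geometry,
    optics: EffectiveOptics,
) -> np.ndarray:
    """Coarse-to-fine inversion of one projection.

    Level j works on data box-averaged j times with pixel size scaled by
    2^j (propagation distance unchanged); ray shifts in pixel units shrink
    by half per level, so the coarsest problem is phase-free and its
    solution is the plain logarithm of the data.  Images not divisible by
    2^(n_levels-1) are edge-padded and cropped on return.
    """
    data = np.asarray(data, dtype=float)
    H, W = data.shape
    m = 2 ** (config.n_levels - 1)
    padH = (-H) % m
    padW = (-W) % m
    padded = np.pad(data, ((0, padH), (0, padW)), mode="edge")

    pyramid = [padded]
    geoms = [replace(geometry, n_rows=padded.shape[0], n_cols=padded.shape[1])]
    for j in range(1, config.n_levels):
        pyramid.append(_box_down(pyramid[-1]))
        geoms.append(geoms[-1].rescaled(2))

    a = -np.log(np.clip(pyramid[-1], 1e-12, None))  # trivial coarse solution
    for j in range(config.n_levels - 1, -1, -1):
        log.info(
            "level %d (%dx%d, pixel %.3g m)",
            j,
            pyramid[j].shape[0],
            pyramid[j].shape[1],
            geoms[j].pixel,
        )
        a = nonlinear_cg(pyramid[j], a, config, bands, geoms[j], optics)
        if j > 0:
            a = _bilinear_up(a)
    return a[:H, :W]
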