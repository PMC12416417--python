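import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from eprtomo.eikonal import (
    ShiftField,
    caustic_mask,
    eikonal_splat,
    eikonal_splat_adjoint,
    epr_forward_jvp,
    epr_forward_model,
    epr_forward_vjp,
    misfit_gradient,
    shift_field,
    _corner_maps,
)
from eprtomo.optics import phase_from_absorption, wavenumber
from eprtomo.paganin import tie_forward

K109 = wavenumber(109.0)


def smooth_shifts(rng, n, sigma, amplitude):
    sx = gaussian_filter(rng.standard_normal((n, n)), sigma)
    sy = gaussian_filter(rng.standard_normal((n, n)), sigma)
    scale = amplitude / max(np.abs(sx).max(), np.abs(sy).max())
    return ShiftField(s_x=sx * scale, s_y=sy * scale)


class TestShiftField:
    def test_constant_phase_no_shift(self, geometry):
        s = shift_field(np.full((8, 8), 2.0), geometry, K109)
        np.testing.assert_array_equal(s.s_x, 0.0)
        np.testing.assert_array_equal(s.s_y, 0.0)

    def test_linear_ramp_uniform_shift(self, geometry):
        c = 1e-3  # rad per pixel
        phi = c * np.arange(16)[None, :] * np.ones((16, 1))
        s = shift_field(phi, geometry, K109)
        expected = geometry.L / (K109 * geometry.pixel**2) * c
        np.testing.assert_allclose(s.s_x, expected, rtol=1e-12)
        np.testing.assert_allclose(s.s_y, 0.0, atol=1e-15)

    def test_gaussian_matches_analytic_gradient(self, geometry):
        n, sig = 64, 6.0
        yy, xx = np.indices((n, n), dtype=float)
        phi = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * sig**2))
        s = shift_field(phi, geometry, K109)
        gx_true = -(xx - 32) / sig**2 * phi
        c = geometry.L / (K109 * geometry.pixel**2)
        # centered differences are 2nd order: error ~ max|phi'''| / 6
        assert np.abs(s.s_x / c - gx_true).max() < 1.0 / (6 * sig**3) * 3

    def test_non_finite_phase_rejected(self, geometry):
        phi = np.zeros((4, 4))
        phi[0, 0] = np.nan
        with pytest.raises(ValueError):
            shift_field(phi, geometry, K109)


class TestEikonalSplat:
    def test_zero_shift_identity(self, rng):
        I = rng.random((20, 20))
        acc = eikonal_splat(I, ShiftField(np.zeros_like(I), np.zeros_like(I)))
        np.testing.assert_array_equal(acc.detector, I)
        assert acc.escaped == 0.0

    def test_integer_translation(self, rng):
        I = rng.random((16, 16))
        acc = eikonal_splat(I, ShiftField(np.full_like(I, 3.0), np.zeros_like(I)))
        np.testing.assert_allclose(acc.detector[:, 3:], I[:, :-3], atol=1e-12)
        assert acc.detector.sum() + acc.escaped == pytest.approx(I.sum(), rel=1e-12)

    def test_conservation_random_smooth_fields(self, rng):
        for _ in range(10):
            I = rng.random((64, 64))
            s = smooth_shifts(rng, 64, 4, rng.uniform(0.5, 6.0))
            acc = eikonal_splat(I, s)
            total = acc.detector.sum() + acc.escaped
            assert total == pytest.approx(I.sum(), rel=1e-10)

    def test_translation_equivariance(self, rng):
        I = np.zeros((32, 32))
        I[8:16, 8:16] = rng.random((8, 8))
        s = smooth_shifts(rng, 32, 3, 1.5)
        out1 = eikonal_splat(I, s).detector
        I2 = np.roll(I, (5, 7), axis=(0, 1))
        s2 = ShiftField(np.roll(s.s_x, (5, 7), (0, 1)), np.roll(s.s_y, (5, 7), (0, 1)))
        out2 = eikonal_splat(I2, s2).detector
        # interior equivariance (corner interpolation pads by replication)
        np.testing.assert_allclose(
            out2[10:26, 12:28], np.roll(out1, (5, 7), (0, 1))[10:26, 12:28], atol=1e-10
        )

    def test_light_escapes_outside_geometric_shadow(self):
        # bright disc whose border rays deflect outward: intensity appears
        # strictly outside the disc's geometric projection, which the
        # linearized propagator cannot represent
        n = 48
        yy, xx = np.indices((n, n), dtype=float)
        r = np.hypot(yy - 24, xx - 24)
        I = (r < 8).astype(float)
        ux, uy = np.where(r > 0, (xx - 24) / np.maximum(r, 1e-9), 0.0), np.where(
            r > 0, (yy - 24) / np.maximum(r, 1e-9), 0.0
        )
        border = (r > 5) & (r < 8)
        s = ShiftField(s_x=5.0 * ux * border, s_y=5.0 * uy * border)
        acc = eikonal_splat(I, s)
        outside = r > 9.5
        assert acc.detector[outside].sum() > 0.1
        assert acc.detector.sum() + acc.escaped == pytest.approx(I.sum(), rel=1e-10)

    def test_folding_adds_intensity(self):
        # two half-planes shifted toward each other: rays cross at the
        # junction and their intensities add (caustic folding)
        n = 32
        I = np.ones((n, n))
        s_x = np.where(np.arange(n)[None, :] < n // 2, 3.0, -3.0) * np.ones((n, 1))
        acc = eikonal_splat(I, ShiftField(s_x, np.zeros_like(s_x)))
        assert acc.detector.max() > 1.5  # overlapping quads accumulate
        assert acc.detector.sum() + acc.escaped == pytest.approx(I.sum(), rel=1e-10)

    def test_non_finite_shift_rejected(self):
        I = np.ones((4, 4))
        s = np.zeros((4, 4))
        s_bad = s.copy()
        s_bad[1, 1] = np.inf
        with pytest.raises(ValueError):
            eikonal_splat(I, ShiftField(s_bad, s))


class TestSplatGeometryOracle:
    """Cross-check the polygon clipping against an exact geometry engine."""

    def test_overlap_areas_match_shapely(self, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon, box

        n = 12
        I = rng.random((n, n))
        s = smooth_shifts(rng, n, 2, 2.5)
        acc = eikonal_splat(I, s)
        cx, cy = _corner_maps(s)
        expected = np.zeros((n, n))
        escaped = 0.0
        for i in range(n):
            for j in range(n):
                quad = Polygon(
                    [
                        (cx[i, j], cy[i, j]),
                        (cx[i, j + 1], cy[i, j + 1]),
                        (cx[i + 1, j + 1], cy[i + 1, j + 1]),
                        (cx[i + 1, j], cy[i + 1, j]),
                    ]
                )
                area = quad.area
                w_in = 0.0
                for r in range(n):
                    for c in range(n):
                        cell = box(c - 0.5, r - 0.5, c + 0.5, r + 0.5)
                        w = quad.intersection(cell).area
                        expected[r, c] += I[i, j] * w / area
                        w_in += w
                escaped += I[i, j] * (1.0 - w_in / area)
        np.testing.assert_allclose(acc.detector, expected, atol=1e-10)
        assert acc.escaped == pytest.approx(escaped, abs=1e-10)

    def test_transport_matches_stratified_ray_casting(self, rng):
        # dense sub-pixel ray casting through the bilinear corner-shift patch
        # converges to the area-weighted splat for smooth fields
        n, m = 16, 96  # m^2 rays per pixel
        I = rng.random((n, n))
        s = smooth_shifts(rng, n, 4, 1.2)
        acc = eikonal_splat(I, s)
        cx, cy = _corner_maps(s)
        out = np.zeros((n, n))
        t = (np.arange(m) + 0.5) / m
        ty, tx = np.meshgrid(t, t, indexing="ij")
        for i in range(n):
            for j in range(n):
                # bilinear map of the unit square spanned by the 4 corners
                px = (
                    cx[i, j] * (1 - tx) * (1 - ty)
                    + cx[i, j + 1] * tx * (1 - ty)
                    + cx[i + 1, j] * (1 - tx) * ty
                    + cx[i + 1, j + 1] * tx * ty
                )
                py = (
                    cy[i, j] * (1 - tx) * (1 - ty)
                    + cy[i, j + 1] * tx * (1 - ty)
                    + cy[i + 1, j] * (1 - tx) * ty
                    + cy[i + 1, j + 1] * tx * ty
                )
                cc = np.floor(px + 0.5).astype(int)
                rr = np.floor(py + 0.5).astype(int)
                ok = (cc >= 0) & (cc < n) & (rr >= 0) & (rr < n)
                np.add.at(out, (rr[ok], cc[ok]), I[i, j] / m**2)
        assert np.abs(out - acc.detector).max() < 6e-3 * I.max()


class TestAdjointAndGradient:
    def test_splat_adjoint_dot_product(self, rng):
        I = rng.random((32, 32))
        s = smooth_shifts(rng, 32, 3, 2.0)
        r = rng.standard_normal((32, 32))
        lhs = np.sum(eikonal_splat(I, s).detector * r)
        rhs = np.sum(I * eikonal_splat_adjoint(r, s))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_jvp_vjp_adjoint_identity(self, rng, geometry, poly_bands, poly_optics):
        a = gaussian_filter(rng.random((32, 32)), 3)
        da = rng.standard_normal((32, 32))
        r = rng.standard_normal((32, 32))
        lhs = np.sum(epr_forward_jvp(a, da, poly_bands, geometry, poly_optics) * r)
        rhs = np.sum(da * epr_forward_vjp(a, r, poly_bands, geometry, poly_optics))
        assert lhs == pytest.approx(rhs, rel=1e-11)

    def test_gradient_zero_at_data(self, rng, geometry, mono_band, mono_optics):
        a = gaussian_filter(rng.random((24, 24)), 3) * 0.5
        data = epr_forward_model(a, mono_band, geometry, mono_optics)
        J, g = misfit_gradient(a, data, mono_band, geometry, mono_optics)
        assert J == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_gradient_matches_fd_of_linearized_objective(
        self, rng, geometry, mono_band, mono_optics
    ):
        a = gaussian_filter(rng.random((32, 32)), 3) * 0.6
        data = epr_forward_model(a, mono_band, geometry, mono_optics)
        data = data + 0.02 * rng.standard_normal(data.shape)
        F0 = epr_forward_model(a, mono_band, geometry, mono_optics)
        _, g = misfit_gradient(a, data, mono_band, geometry, mono_optics, forward=F0)
        eps = 1e-5
        for _ in range(5):
            d = gaussian_filter(rng.standard_normal((32, 32)), 1)
            dF = epr_forward_jvp(a, d, mono_band, geometry, mono_optics)
            Jp = np.sum((F0 + eps * dF - data) ** 2)
            Jm = np.sum((F0 - eps * dF - data) ** 2)
            fd = (Jp - Jm) / (2 * eps)
            assert np.sum(g * d) == pytest.approx(fd, rel=1e-4)

    def test_gradient_support_is_local(self, geometry, mono_band, mono_optics):
        a = np.zeros((32, 32))
        data = epr_forward_model(a, mono_band, geometry, mono_optics)
        data[16, 16] += 0.1  # single-pixel data perturbation
        _, g = misfit_gradient(a, data, mono_band, geometry, mono_optics)
        far = np.ones((32, 32), bool)
        far[10:23, 10:23] = False
        assert np.abs(g[far]).max() < 1e-12 * np.abs(g).max()


class TestForwardModel:
    def test_zero_absorption_unity(self, geometry, poly_bands, poly_optics):
        out = epr_forward_model(np.zeros((24, 24)), poly_bands, geometry, poly_optics)
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_first_order_agreement_with_tie(self, geometry, mono_band, mono_optics):
        # relative discrepancy |epr - tie| / |tie - 1| vanishes with amplitude
        n = 96
        yy, xx = np.indices((n, n), dtype=float)
        base = np.exp(-((yy - 48) ** 2 + (xx - 48) ** 2) / (2 * 8.0**2))
        rel = []
        for amp in (0.5, 0.05):
            a = amp * base
            phi = phase_from_absorption(a, mono_optics)
            epr = epr_forward_model(a, mono_band, geometry, mono_optics)
            tie = tie_forward(
                np.exp(-a), phi, geometry, mono_optics.k, bc="periodic", stencil="wide"
            )
            rel.append(np.abs(epr - tie).max() / np.abs(tie - 1.0).max())
        assert rel[1] < 0.5 * rel[0]

    def test_caustic_mask_flags_folds(self):
        n = 32
        s_x = np.zeros((n, n))
        s_x[:, :16] = np.linspace(0, 8, 16)[None, :]  # strong compression
        mask = caustic_mask(ShiftField(s_x, np.zeros_like(s_x)))
        assert mask.any()
        assert not caustic_mask(ShiftField(np.zeros((4, 4)), np.zeros((4, 4)))).any()
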