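import numpy as np
import pytest

from eprtomo.optics import Geometry, OpticalConstants, wavenumber
from eprtomo.synthetic import (
    Phantom,
    Primitive,
    SimulationConfig,
    bone_shell_phantom,
    flat_spectrum,
    fresnel_oracle,
    ground_truth_absorption,
    make_spot_image,
    phantom_density_slice,
    project_phantom,
    simulate_measurement,
)


@pytest.fixture
def disc_phantom(constants):
    return Phantom(
        (Primitive(10.0, -5.0, 12.0, 12.0, constants, 0, 2),), 2, 64, 28e-6
    )


class TestProjectPhantom:
    def test_central_chord_is_diameter(self, constants):
        ph = Phantom((Primitive(0.0, 0.0, 10.0, 10.0, constants, 0, 1),), 1, 65, 1e-6)
        (a, phi), = project_phantom(ph, 0.0, [109.0])
        k = wavenumber(109.0)
        _, b = constants(109.0)
        # center column crosses the full diameter 2R
        assert a[0, 32] == pytest.approx(2 * k * b * 20.0 * 1e-6, rel=1e-12)
        d, _ = constants(109.0)
        assert phi[0, 32] == pytest.approx(-k * d * 20.0 * 1e-6, rel=1e-12)

    def test_disjoint_primitives_add(self, constants):
        p1 = Primitive(-15.0, 0.0, 5.0, 5.0, constants, 0, 1)
        p2 = Primitive(15.0, 0.0, 5.0, 5.0, constants, 0, 1)
        ph12 = Phantom((p1, p2), 1, 64, 1e-6)
        a12 = project_phantom(ph12, 0.3, [100.0])[0][0]
        a1 = project_phantom(Phantom((p1,), 1, 64, 1e-6), 0.3, [100.0])[0][0]
        a2 = project_phantom(Phantom((p2,), 1, 64, 1e-6), 0.3, [100.0])[0][0]
        np.testing.assert_allclose(a12, a1 + a2, rtol=1e-12)

    def test_centered_phantom_symmetric_under_pi(self, constants):
        ph = Phantom((Primitive(0.0, 0.0, 8.0, 12.0, constants, 0, 1),), 1, 65, 1e-6)
        a0 = project_phantom(ph, 0.4, [100.0])[0][0]
        a_pi = project_phantom(ph, 0.4 + np.pi, [100.0])[0][0]
        np.testing.assert_allclose(a0[0], a_pi[0, ::-1], atol=1e-10)

    def test_angle_range_checked(self, disc_phantom):
        with pytest.raises(ValueError):
            project_phantom(disc_phantom, -0.1, [100.0])


class TestFresnelOracle:
    def test_plane_wave_unchanged(self):
        u = np.ones((64, 64), complex)
        I = fresnel_oracle(u, 10.0, 1e-11, 28e-6)
        np.testing.assert_allclose(I, 1.0, atol=1e-12)

    def test_half_talbot_phase_grating(self):
        # weak sinusoidal phase grating, half-Talbot distance: contrast is
        # maximal with I = 1 + 2 eps cos(2 pi x / p)
        lam = 2 * np.pi / wavenumber(109.0)
        pixel = 28e-6
        p = 32 * pixel
        L = p**2 / (2 * lam)
        n = 256
        x = np.arange(n) * pixel
        eps = 1e-3
        u = np.exp(1j * eps * np.cos(2 * np.pi * x / p))[None, :] * np.ones((n, 1))
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                I = fresnel_oracle(u, L, lam, pixel)
        pred = 1 + 2 * eps * np.cos(2 * np.pi * x / p)
        assert np.abs(I[0] - pred).max() < 1e-3 * eps * 2

    def test_energy_conserved(self, rng):
        u = np.exp(1j * rng.standard_normal((64, 64)) * 0.1)
        I = fresnel_oracle(u, 1.0, 1e-11, 28e-6)
        assert I.sum() == pytest.approx(np.abs(u**2).sum(), rel=1e-10)


class TestSimulateMeasurement:
    def test_empty_phantom_normalizes_to_unity(self, flat_spec, constants):
        ph = Phantom((), 8, 32, 28e-6)
        cfg = SimulationConfig(
            spectrum=flat_spec, geometry=Geometry(L=30.0, pixel=28e-6), n_bands=3
        )
        ds = simulate_measurement(ph, cfg, np.array([0.0, 0.5]))
        np.testing.assert_allclose(ds.normalized, 1.0, atol=1e-12)

    def test_fixed_seed_reproduces_bit_identical(self, flat_spec, constants, disc_phantom):
        cfg = SimulationConfig(
            spectrum=flat_spec,
            geometry=Geometry(L=30.0, pixel=28e-6),
            n_bands=3,
            flux=1e4,
            seed=42,
        )
        ds1 = simulate_measurement(disc_phantom, cfg, np.array([0.0, 1.0]))
        ds2 = simulate_measurement(disc_phantom, cfg, np.array([0.0, 1.0]))
        np.testing.assert_array_equal(ds1.raw, ds2.raw)
        np.testing.assert_array_equal(ds1.flats, ds2.flats)

    def test_weak_phantom_matches_tie_in_the_near_field(self, flat_spec, constants):
        # noiseless, blur-free simulation of a weak smooth phantom agrees
        # with the per-band linearized propagator; the residual is the
        # higher-order Fresnel correction and shrinks with the propagation
        # distance
        from eprtomo.optics import equal_area_bands
        from eprtomo.paganin import tie_forward
        from eprtomo.synthetic import _soft_ellipse

        weak = OpticalConstants(
            constants.energies, constants.delta * 0.02, constants.beta * 0.02
        )
        prims = tuple(_soft_ellipse(0.0, 0.0, 10.0, 10.0, weak, 0, 16, 1.0, 6.0, 8))
        ph = Phantom(prims, 16, 64, 28e-6)
        ratios = []
        for L in (30.0, 5.0):
            geo = Geometry(L=L, pixel=28e-6)
            cfg = SimulationConfig(spectrum=flat_spec, geometry=geo, n_bands=3)
            ds = simulate_measurement(ph, cfg, np.array([0.0]))
            pred = np.zeros((16, 64))
            for (_, f, om) in equal_area_bands(flat_spec, 3):
                (a_e, phi_e), = project_phantom(ph, 0.0, [om])
                pred += f * tie_forward(
                    np.exp(-a_e), phi_e, geo, wavenumber(om), bc="periodic"
                )
            signal = np.sqrt(np.mean((ds.normalized[0] - 1.0) ** 2))
            resid = np.sqrt(np.mean((ds.normalized[0] - pred) ** 2))
            ratios.append(resid / signal)
        assert ratios[1] < 0.15
        assert ratios[1] < 0.5 * ratios[0]

    def test_source_blur_smooths(self, flat_spec, constants, disc_phantom):
        geo = Geometry(L=30.0, pixel=28e-6)
        sharp = simulate_measurement(
            disc_phantom,
            SimulationConfig(spectrum=flat_spec, geometry=geo, n_bands=2),
            np.array([0.0]),
        )
        blurred = simulate_measurement(
            disc_phantom,
            SimulationConfig(
                spectrum=flat_spec,
                geometry=geo,
                n_bands=2,
                source_fwhm=500e-6,
                source_distance=145.0,
            ),
            np.array([0.0]),
        )
        assert np.abs(np.diff(blurred.normalized[0], axis=1)).max() < np.abs(
            np.diff(sharp.normalized[0], axis=1)
        ).max()


class TestSpotImage:
    def test_zero_tail_halo_is_empty(self):
        spot = make_spot_image(0.0, 0.05, spot_radius=3.0, flux=np.inf, shape=(64, 64))
        assert spot.pixels[~spot.spot_mask].max() == pytest.approx(0.0, abs=1e-12)

    def test_halo_fraction_approximates_f(self):
        f = 0.3
        spot = make_spot_image(f, 0.1, spot_radius=2.0, flux=np.inf)
        halo = spot.pixels[~spot.spot_mask].sum()
        # part of the tail lands back inside the spot mask, so the halo
        # fraction sits slightly below f
        ratio = halo / spot.pixels.sum()
        assert f - 0.05 < ratio < f + 0.01


class TestBoneShellPhantom:
    def test_scaled_phantom_matches_projection(self, ):
        # the supersampled phantom projects to the same profile (pixel units)
        ph1 = bone_shell_phantom(n=128, n_rows=1, pixel=28e-6)
        ph2 = bone_shell_phantom(n=256, n_rows=1, pixel=14e-6, scale=2)
        a1 = ground_truth_absorption(ph1, 0.7, 109.0)[0]
        a2 = ground_truth_absorption(ph2, 0.7, 109.0)[0].reshape(128, 2).mean(axis=1)
        assert np.abs(a1 - a2).max() < 0.08 * a1.max()

    def test_density_slice_consistent_with_projection(self):
        ph = bone_shell_phantom(n=128, n_rows=1, pixel=28e-6)
        gt = phantom_density_slice(ph, 109.0)
        sino = ground_truth_absorption(ph, 0.0, 109.0)[0]
        # the ray at angle 0 runs along +x (axis 1); summing the density
        # slice along it reproduces the sinogram row up to edge pixelation
        np.testing.assert_allclose(gt.sum(axis=1), sino, atol=0.05 * sino.max())
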