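"""Forward-simulator physics: speckle statistics, retardance accumulation,
energy decay, repeat behaviour and the axial point-spread function."""

import numpy as np
import pytest
from scipy import stats

from jmoct import (PhantomSpec, LayerProperty, SystemProfile,
                   simulate_jones_volume, simulate_point_reflector,
                   uniform_phantom, measure_axial_fwhm)
from jmoct.phantom import _linear_retarder

from conftest import small_system


class TestForwardModel:
    def test_identity_medium_matrices_proportional_to_identity(self, uniform_jones):
        jv = uniform_jones(mu=0.0, dn=0.0)
        M = jv.data[0]
        assert np.allclose(M[..., 0, 1], 0) and np.allclose(M[..., 1, 0], 0)
        assert np.allclose(M[..., 0, 0], M[..., 1, 1])
        # no attenuation: mean intensity stationary in depth
        prof = (np.abs(M[..., 0, 0]) ** 2).mean(axis=(1, 2))
        assert np.all(np.abs(prof / prof.mean() - 1) < 0.25)

    def test_same_seed_bit_identical(self):
        spec = uniform_phantom(2.0, 1e-3, system=small_system(noise_floor_db=-30),
                               seed=7)
        a = simulate_jones_volume(spec)
        b = simulate_jones_volume(spec)
        assert np.array_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        sys_ = small_system()
        a = simulate_jones_volume(uniform_phantom(2.0, system=sys_, seed=1))
        b = simulate_jones_volume(uniform_phantom(2.0, system=sys_, seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_retardance_accumulation_matches_matrix_product_oracle(self):
        """Round-trip retardance over 3 pixels of a 2.2e-3 retarder equals
        4π·Δn·L·Δ/λ0 = 0.458 rad, and agrees with an explicit 2×2 retarder
        chain product."""
        dn, lag = 2.2e-3, 3
        sys_ = small_system(x_pixels=2, y_pixels=2)
        jv = simulate_jones_volume(uniform_phantom(0.0, dn, system=sys_, seed=0),
                                   psf=False)
        M1, M2 = jv.data[0, 10, 0, 0], jv.data[0, 10 + lag, 0, 0]
        L = M2 @ np.linalg.inv(M1)
        lam = np.linalg.eigvals(L)
        delta = abs(np.angle(lam[0] / lam[1]))

        expected = 4 * np.pi * dn * lag * sys_.axial_pixel / sys_.center_wavelength
        assert expected == pytest.approx(0.458, abs=5e-4)
        assert delta == pytest.approx(expected, abs=1e-9)

        # independent oracle: chain product of per-voxel single-pass retarders
        phi = 2 * np.pi / sys_.center_wavelength * dn * sys_.axial_pixel
        J = _linear_retarder(np.array(phi), np.array(0.3))
        T = np.linalg.matrix_power(J, lag)
        lam_o = np.linalg.eigvals(T.T @ T)
        assert abs(np.angle(lam_o[0] / lam_o[1])) == pytest.approx(expected, abs=1e-12)

    def test_energy_decay_exponential(self):
        """Lateral-mean intensity of a noise-free uniform phantom decays as
        exp(-2 mu z); regression slope within 1%."""
        mu = 2.0
        sys_ = small_system(depth_pixels=300, x_pixels=48, y_pixels=48)
        jv = simulate_jones_volume(uniform_phantom(mu, system=sys_, seed=3))
        prof = (np.abs(jv.data[0]) ** 2).mean(axis=(1, 2, 3, 4))
        z = np.arange(300) * sys_.axial_pixel_mm
        sl = slice(10, 280)
        slope = np.polyfit(z[sl], np.log(prof[sl]), 1)[0]
        assert slope == pytest.approx(-2 * mu, rel=0.01)

    def test_polarization_consistency_unitary_eigenvalues(self, uniform_jones):
        """Without depolarization, PSF and noise, every voxel matrix is a
        scalar times a unitary retarder: its eigenvalue magnitudes agree."""
        jv = uniform_jones(mu=1.0, dn=1.5e-3)
        lam = np.linalg.eigvals(jv.data[0].reshape(-1, 2, 2))
        mags = np.abs(lam)
        assert np.max(np.abs(mags[:, 0] - mags[:, 1]) /
                      np.maximum(mags.max(axis=1), 1e-300)) < 1e-10

    def test_speckle_intensity_is_exponential(self):
        """Fully developed speckle: channel intensity is exponentially
        distributed (KS at alpha=0.01 on at least 9 of 10 seeds)."""
        passed = 0
        for seed in range(10):
            sys_ = small_system(depth_pixels=8, x_pixels=24, y_pixels=24)
            jv = simulate_jones_volume(uniform_phantom(0.0, system=sys_, seed=seed),
                                       psf=False)
            I = np.abs(jv.data[0, :, :, :, 0, 0].ravel()) ** 2
            p = stats.kstest(I / I.mean(), "expon").pvalue
            passed += p > 0.01
        assert passed >= 9

    def test_repeat_correlation_static_vs_flow(self):
        sys_ = small_system(n_repeats=4, noise_floor_db=-60, depth_pixels=48,
                            x_pixels=24, y_pixels=24)
        labels = np.zeros(sys_.grid_shape, np.int16)
        labels[24:] = 1
        props = {0: LayerProperty("static", mu_atten=0.5),
                 1: LayerProperty("flow", mu_atten=0.5, flow=True)}
        jv = simulate_jones_volume(PhantomSpec(labels, props, sys_, seed=9),
                                   psf=False)
        E = jv.data[..., 0, 0]
        num = (E[:-1] * np.conj(E[1:])).sum(axis=0)
        den = np.sqrt((np.abs(E[:-1]) ** 2).sum(axis=0) *
                      (np.abs(E[1:]) ** 2).sum(axis=0))
        rho = np.abs(num) / den
        assert rho[labels == 0].mean() > 0.99
        assert rho[labels == 1].mean() < 0.5

    def test_shape_mismatch_names_both_shapes(self):
        sys_ = small_system()
        labels = np.zeros((4, 4, 4), np.int16)
        with pytest.raises(ValueError, match=r"\(4, 4, 4\).*\(64, 16, 16\)"):
            PhantomSpec(labels, {0: LayerProperty("x")}, sys_)

    def test_missing_label_property_rejected(self):
        sys_ = small_system()
        labels = np.ones(sys_.grid_shape, np.int16)
        with pytest.raises(ValueError, match="labels \\[1\\]"):
            PhantomSpec(labels, {0: LayerProperty("x")}, sys_)


class TestPointReflector:
    def test_axial_fwhm_matches_system_resolution(self):
        sys_ = SystemProfile(x_pixels=1, y_pixels=1, n_repeats=1,
                             noise_floor_db=None)
        fwhm = measure_axial_fwhm(simulate_point_reflector(sys_))
        assert abs(fwhm - sys_.axial_fwhm) < sys_.axial_pixel / 2

    def test_fwhm_scales_linearly(self):
        base = SystemProfile(x_pixels=1, y_pixels=1, n_repeats=1,
                             noise_floor_db=None)
        wide = base.with_(axial_fwhm=28.0)
        f1 = measure_axial_fwhm(simulate_point_reflector(base))
        f2 = measure_axial_fwhm(simulate_point_reflector(wide))
        assert f2 == pytest.approx(2 * f1, rel=0.05)

    def test_reflector_position_is_argmax(self):
        sys_ = SystemProfile(x_pixels=1, y_pixels=1, n_repeats=1,
                             depth_pixels=120, noise_floor_db=None)
        for k in (30, 77):
            jv = simulate_point_reflector(sys_, pixel=k)
            I = (np.abs(jv.data[0, :, 0, 0]) ** 2).mean(axis=(-2, -1))
            assert int(np.argmax(I)) == k

    def test_too_shallow_volume_rejected(self):
        sys_ = SystemProfile(x_pixels=1, y_pixels=1, depth_pixels=12,
                             noise_floor_db=None)
        with pytest.raises(ValueError, match="shallow"):
            simulate_point_reflector(sys_)
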