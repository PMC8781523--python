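"""Contrast estimators: intensity, attenuation, local birefringence, DOPU,
angiography and the SNR mask."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jmoct import (ContrastVolume, LayerProperty, PhantomSpec,
                   compute_attenuation, compute_dopu, compute_intensity,
                   compute_local_birefringence, compute_octa, snr_mask,
                   attenuation_analysis_window, simulate_jones_volume,
                   uniform_phantom)

from conftest import small_system

DZ = 0.00724  # depth pixel in mm


def exponential_intensity(mu, n=2000, nx=2, ny=2, i0=1.0):
    prof = i0 * np.exp(-2.0 * mu * DZ * np.arange(n))
    return ContrastVolume(np.tile(prof[:, None, None], (1, nx, ny)),
                          kind="intensity_linear")


class TestIntensity:
    def test_unit_matrix(self):
        sys_ = small_system(depth_pixels=4, x_pixels=2, y_pixels=2)
        data = np.zeros((1, 4, 2, 2, 2, 2), complex)
        data[..., 0, 0] = data[..., 1, 1] = 1.0
        from jmoct import JonesVolume
        jv = JonesVolume(data, sys_)
        lin = compute_intensity(jv)
        assert np.allclose(lin.data, 0.5)   # mean of (1, 0, 0, 1)
        db = compute_intensity(jv, kind="intensity_db")
        assert np.allclose(db.data, 10 * np.log10(0.5))

    def test_scaled_diagonal(self):
        sys_ = small_system(depth_pixels=2, x_pixels=1, y_pixels=1)
        data = np.zeros((1, 2, 1, 1, 2, 2), complex)
        a = 2.0  # |a|^2 = 4
        data[..., 0, 0] = data[..., 1, 1] = a
        from jmoct import JonesVolume
        lin = compute_intensity(JonesVolume(data, sys_))
        assert np.allclose(lin.data, 2.0)   # mean of (4, 0, 0, 4)


class TestAttenuation:
    def test_log_corrected_exact_on_discrete_exponential(self):
        mu = 2.0
        att = compute_attenuation(exponential_intensity(mu), DZ,
                                  method="log_corrected", tail_guard=0,
                                  tail_fit_pixels=32)
        assert np.abs(att.data[att.valid_mask] - mu).max() < 1e-11

    def test_raw_matches_geometric_series_closed_form(self):
        mu = 2.0
        att = compute_attenuation(exponential_intensity(mu), DZ, method="raw",
                                  tail_guard=0, tail_fit_pixels=32)
        expected = (np.exp(2 * mu * DZ) - 1) / (2 * DZ)
        assert expected == pytest.approx(2.029, abs=5e-4)
        assert np.abs(att.data[att.valid_mask] - expected).max() < 1e-12

    @settings(deadline=None, max_examples=25)
    @given(mu=st.floats(0.2, 12.0), pitch=st.floats(0.004, 0.012))
    def test_log_estimator_exact_for_any_rate_and_pitch(self, mu, pitch):
        prof = np.exp(-2.0 * mu * pitch * np.arange(600))
        cv = ContrastVolume(prof[:, None, None], kind="intensity_linear")
        att = compute_attenuation(cv, pitch, tail_guard=0, tail_fit_pixels=32)
        assert np.abs(att.data[att.valid_mask] - mu).max() < 1e-9 * mu

    def test_all_zero_line_flagged_invalid_not_raised(self):
        data = np.ones((50, 3, 3))
        data[:, 1, 1] = 0.0
        att = compute_attenuation(ContrastVolume(data, kind="intensity_linear"),
                                  DZ, tail_guard=4)
        assert not att.valid_mask[:, 1, 1].any()
        assert att.valid_mask[:10, 0, 0].all()

    def test_speckled_uniform_recovery_high_attenuation(self):
        mu = 11.6
        sys_ = small_system(depth_pixels=400, x_pixels=32, y_pixels=32,
                            noise_floor_db=-30)
        jv = simulate_jones_volume(uniform_phantom(mu, system=sys_, seed=11),
                                   psf=True)
        I = compute_intensity(jv)
        att = compute_attenuation(I, DZ, noise_floor=sys_.noise_variance,
                                  tail_fit_pixels=32)
        roi = att.valid_mask & attenuation_analysis_window(I, sys_.noise_variance)
        assert att.data[roi].mean() == pytest.approx(mu, rel=0.05)

    def test_rejects_unknown_method_and_wrong_kind(self):
        cv = exponential_intensity(1.0, n=50)
        with pytest.raises(ValueError, match="method"):
            compute_attenuation(cv, DZ, method="magic")
        db = ContrastVolume(np.zeros((50, 2, 2)), kind="intensity_db")
        with pytest.raises(ValueError, match="linear"):
            compute_attenuation(db, DZ)


class TestLocalBirefringence:
    @pytest.mark.parametrize("aggregation", ["trace", "median"])
    def test_noise_free_uniform_retarder_recovered_exactly(self, aggregation):
        dn = 1.6e-3
        sys_ = small_system(depth_pixels=64, x_pixels=8, y_pixels=8)
        jv = simulate_jones_volume(uniform_phantom(0.5, dn, system=sys_, seed=1),
                                   psf=False)
        out = compute_local_birefringence(jv, snr_threshold_db=None,
                                          aggregation=aggregation)
        vals = out.data[out.valid_mask]
        assert np.abs(vals - dn).max() < 1e-12
        # implied local retardance: 4*pi*dn*lag*dz/lambda = 0.333 rad
        delta = vals.mean() * 4 * np.pi * 3 * 7.24 / 1.31
        assert delta == pytest.approx(0.333, abs=5e-4)

    def test_isotropic_medium_gives_zero(self, uniform_jones):
        jv = uniform_jones(mu=0.5, dn=0.0)
        out = compute_local_birefringence(jv, snr_threshold_db=None)
        assert np.abs(out.data[out.valid_mask]).max() < 1e-9

    def test_above_wrap_limit_aliases(self):
        sys_ = small_system(depth_pixels=64, x_pixels=4, y_pixels=4)
        lag = 3
        wrap_limit = sys_.center_wavelength / (4 * lag * sys_.axial_pixel)
        dn = 0.018
        assert dn > wrap_limit
        jv = simulate_jones_volume(uniform_phantom(0.0, dn, system=sys_, seed=1),
                                   psf=False)
        out = compute_local_birefringence(jv, lag=lag, snr_threshold_db=None)
        delta_true = np.pi * dn / wrap_limit
        expected = (2 * np.pi - delta_true) / np.pi * wrap_limit
        vals = out.data[out.valid_mask]
        assert np.allclose(vals, expected, atol=1e-9)

    def test_lag_must_be_smaller_than_depth(self, uniform_jones):
        jv = uniform_jones()
        with pytest.raises(ValueError, match="lag"):
            compute_local_birefringence(jv, lag=64)


class TestDopu:
    def test_uniform_polarization_gives_one(self, uniform_jones):
        # isotropic medium: every voxel scatters in the same polarization state
        out = compute_dopu(uniform_jones(mu=0.5, dn=0.0), kernel=(5, 5))
        assert np.allclose(out.data, 1.0, atol=1e-9)

    def test_fully_scrambled_region_falls_low(self):
        sys_ = small_system(depth_pixels=48, x_pixels=32, y_pixels=32)
        spec = uniform_phantom(0.2, system=sys_, depol_fraction=1.0, seed=4)
        out = compute_dopu(simulate_jones_volume(spec, psf=False), kernel=(5, 5))
        assert out.data[5:-5].mean() < 0.35

    def test_monotone_in_depol_fraction(self):
        means = []
        for p in (0.0, 0.2, 0.5, 0.8, 1.0):
            sys_ = small_system(depth_pixels=40, x_pixels=24, y_pixels=24)
            spec = uniform_phantom(0.2, 1e-3, system=sys_, depol_fraction=p,
                                   seed=8)
            out = compute_dopu(simulate_jones_volume(spec), kernel=(3, 3))
            means.append(out.data[4:-4].mean())
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_kernel_validation(self, uniform_jones):
        jv = uniform_jones()
        with pytest.raises(ValueError, match="odd"):
            compute_dopu(jv, kernel=(2, 3))
        with pytest.raises(ValueError, match="larger"):
            compute_dopu(jv, kernel=(65, 3))


class TestOcta:
    def test_identical_repeats_give_zero_flow(self):
        sys_ = small_system(n_repeats=4)
        spec = uniform_phantom(0.5, system=sys_, seed=2)
        jv = simulate_jones_volume(spec)          # static, no noise
        out = compute_octa(jv, snr_threshold_db=None)
        assert np.abs(out.data).max() < 1e-9

    def test_single_repeat_rejected_with_guidance(self, uniform_jones):
        with pytest.raises(ValueError, match="repeat"):
            compute_octa(uniform_jones())

    def test_flow_and_static_regions_separate(self):
        sys_ = small_system(n_repeats=4, noise_floor_db=-40, depth_pixels=64,
                            x_pixels=32, y_pixels=24)
        labels = np.zeros(sys_.grid_shape, np.int16)
        labels[28:44, 8:24] = 1
        props = {0: LayerProperty("static", mu_atten=0.5),
                 1: LayerProperty("flow", mu_atten=0.5, flow=True)}
        jv = simulate_jones_volume(PhantomSpec(labels, props, sys_, seed=6),
                                   psf=False)   # voxel-crisp flow boundaries
        out = compute_octa(jv, snr_threshold_db=None)
        flow_interior = out.data[31:41, 11:21]
        static = out.data[5:20]
        assert flow_interior.mean() > 0.8
        assert static.mean() < 0.1


class TestSnrMask:
    def test_infinite_thresholds(self):
        cv = exponential_intensity(1.0, n=50)
        assert snr_mask(cv, -np.inf).all()
        assert not snr_mask(cv, np.inf).any()

    def test_crossing_depth_matches_closed_form(self):
        mu, floor = 2.0, 1e-3
        cv = exponential_intensity(mu, n=800)
        mask = snr_mask(cv, 6.0, noise_floor=floor)
        crossing = int(mask[:, 0, 0].sum())
        # exp(-2 mu z) = 10^0.6 * floor
        expected = np.log(1 / (10 ** 0.6 * floor)) / (2 * mu * DZ)
        assert abs(crossing - expected) <= 2
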