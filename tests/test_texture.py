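"""Fourier spectra, spatial indices and the 37-parameter suite.

The angular/radial reductions are checked against an independent
brute-force per-pixel implementation, and the spatial indices against
closed-form DFT expectations for single-cosine surfaces.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringtex.maps import SurfaceMap
from ringtex.synthetic import SurfaceConfig, generate_surface
from ringtex.texture import (
    PARAMETER_NAMES,
    SpectrumOptions,
    amplitude_spectrum,
    angular_spectrum,
    parameter_suite,
    r_half,
    radial_spectrum,
    s_hw,
    s_rwi,
    s_tdi,
)


def brute_force_spectra(values, m_lines=None):
    """Independent per-pixel loop implementation of both reductions."""
    m = values.shape[0]
    if m_lines is None:
        m_lines = m
    amp = np.abs(np.fft.fftshift(np.fft.fft2(values - values.mean())))
    c = m // 2
    angular = np.zeros(m_lines)
    radial = np.zeros(c - 1)
    for row in range(m):
        for col in range(m):
            dy, dx = row - c, col - c
            if not (dy > 0 or (dy == 0 and dx > 0)):
                continue
            ang = math.atan2(dy, dx)
            best = min(
                range(m_lines),
                key=lambda i: min(
                    abs(ang - i * math.pi / m_lines),
                    math.pi - abs(ang - i * math.pi / m_lines),
                ),
            )
            angular[best] += amp[row, col]
            r = int(round(math.hypot(dx, dy)))
            if 1 <= r <= c - 1:
                radial[r - 1] += amp[row, col]
    return angular, radial


def cosine_map(m, wavelength_px, pitch=20.0, angle=0.0, amplitude=1.0):
    y, x = np.mgrid[0:m, 0:m].astype(float)
    u = x * math.cos(angle) + y * math.sin(angle)
    return SurfaceMap(amplitude * np.cos(2 * np.pi * u / wavelength_px), pitch)


class TestAmplitudeSpectrum:
    def test_constant_map_zero_outside_dc(self):
        spec = amplitude_spectrum(SurfaceMap(np.full((32, 32), 7.0), 20.0))
        assert np.allclose(spec.amplitude2d, 0.0, atol=1e-9)

    def test_single_cosine_two_peaks(self):
        m = 64
        spec = amplitude_spectrum(cosine_map(m, m / 8))  # 8 cycles along x
        amp = spec.amplitude2d
        c = m // 2
        peaks = np.argwhere(amp > amp.max() / 2)
        assert len(peaks) == 2
        assert {tuple(p) for p in peaks} == {(c, c + 8), (c, c - 8)}

    def test_modulus_invariant_under_circular_shift(self, rng):
        z = rng.standard_normal((32, 32))
        a = amplitude_spectrum(SurfaceMap(z, 20.0)).amplitude2d
        b = amplitude_spectrum(SurfaceMap(np.roll(z, (5, 11), (0, 1)), 20.0)).amplitude2d
        assert np.allclose(a, b, atol=1e-8)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError):
            SurfaceMap(np.zeros((8, 16)), 20.0)


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_angular_and_radial_match_loop(self, seed):
        z = np.random.default_rng(seed).standard_normal((32, 32))
        spec = amplitude_spectrum(SurfaceMap(z, 20.0))
        ang = angular_spectrum(spec)
        rad = radial_spectrum(spec)
        ang_b, rad_b = brute_force_spectra(z)
        assert np.allclose(ang, ang_b, rtol=1e-12, atol=1e-9)
        assert np.allclose(rad, rad_b, rtol=1e-12, atol=1e-9)

    def test_radial_sum_conserves_inner_amplitudes(self, rng):
        z = rng.standard_normal((32, 32))
        spec = amplitude_spectrum(SurfaceMap(z, 20.0))
        rad = radial_spectrum(spec)
        c = 16
        total = 0.0
        for row in range(32):
            for col in range(32):
                dy, dx = row - c, col - c
                if (dy > 0 or (dy == 0 and dx > 0)) and 1 <= round(
                    math.hypot(dx, dy)
                ) <= c - 1:
                    total += spec.amplitude2d[row, col]
        assert rad.sum() == pytest.approx(total, rel=1e-12)


class TestSpatialIndices:
    def test_stdi_uniform_angular_is_one(self):
        spec = amplitude_spectrum(SurfaceMap(np.zeros((32, 32)), 20.0))
        spec.angular = np.full(32, 3.0)
        assert s_tdi(spec) == pytest.approx(1.0)

    def test_stdi_single_line_is_one_over_m(self):
        spec = amplitude_spectrum(SurfaceMap(np.zeros((32, 32)), 20.0))
        a = np.zeros(32)
        a[5] = 2.0
        spec.angular = a
        assert s_tdi(spec) == pytest.approx(1.0 / 32)

    def test_stdi_striped_surface_near_zero_isotropic_higher(self, rng):
        striped = cosine_map(64, 8)
        spec_s = amplitude_spectrum(striped)
        angular_spectrum(spec_s)
        noise = SurfaceMap(rng.standard_normal((64, 64)), 20.0)
        spec_n = amplitude_spectrum(noise)
        angular_spectrum(spec_n)
        assert s_tdi(spec_s) < 0.1
        assert s_tdi(spec_n) > 5 * s_tdi(spec_s)

    def test_oriented_cosine_argmax_angle(self):
        # stripes varying along x: wave vector on the alpha = 0 line
        spec = amplitude_spectrum(cosine_map(64, 8, angle=0.0))
        ang = angular_spectrum(spec)
        assert np.argmax(ang) == 0
        # stripes varying along y: wave vector at alpha = pi/2
        spec2 = amplitude_spectrum(cosine_map(64, 8, angle=math.pi / 2))
        ang2 = angular_spectrum(spec2)
        assert np.argmax(ang2) == 32  # i * pi / 64 = pi/2

    def test_srwi_pure_wavelength_low_white_noise_high(self, rng):
        spec = amplitude_spectrum(cosine_map(64, 8))
        radial_spectrum(spec)
        low = s_rwi(spec)
        assert low < 0.1
        vals = []
        for seed in range(20):
            z = np.random.default_rng(seed).standard_normal((64, 64))
            sp = amplitude_spectrum(SurfaceMap(z, 20.0))
            radial_spectrum(sp)
            vals.append(s_rwi(sp))
        # with semicircle *sums*, bin population grows linearly with radius,
        # so a flat per-pixel spectrum gives beta(r) ~ r and mean/max ~ 1/2 —
        # far above the single-wavelength value, though not near 1
        assert np.mean(vals) > 5 * low
        assert 0.4 < np.mean(vals) < 0.6

    def test_all_zero_spectrum_gives_nan(self):
        spec = amplitude_spectrum(SurfaceMap(np.zeros((32, 32)), 20.0))
        angular_spectrum(spec)
        radial_spectrum(spec)
        assert math.isnan(s_tdi(spec))
        assert math.isnan(s_rwi(spec))
        assert math.isnan(s_hw(spec))


class TestShw:
    def test_pure_cosine_half_wavelength(self):
        # wavelength 1000 nm on a 256 grid at 20 nm/px: r = 5120/1000 = 5.12
        m, pitch = 256, 20.0
        wavelength_px = 1000.0 / pitch
        spec = amplitude_spectrum(cosine_map(m, wavelength_px, pitch))
        radial_spectrum(spec)
        got = s_hw(spec, pitch)
        # one radial bin of interpolation slack around the ideal 500 nm
        r_ideal = m * pitch / 1000.0
        lo = pitch * (m - 1) / (2 * (r_ideal + 1))
        hi = pitch * (m - 1) / (2 * (r_ideal - 1))
        assert lo < got < hi

    def test_amplitude_invariance(self, rng):
        z = rng.standard_normal((64, 64))
        a = amplitude_spectrum(SurfaceMap(z, 20.0))
        radial_spectrum(a)
        b = amplitude_spectrum(SurfaceMap(10.0 * z, 20.0))
        radial_spectrum(b)
        assert s_hw(a) == pytest.approx(s_hw(b), rel=1e-9)

    def test_halving_switch(self, rng):
        z = rng.standard_normal((64, 64))
        spec = amplitude_spectrum(SurfaceMap(z, 20.0))
        radial_spectrum(spec)
        assert s_hw(spec, options=SpectrumOptions(halve_shw=False)) == pytest.approx(
            2.0 * s_hw(spec), rel=1e-12
        )

    def test_normalized_cumulative_at_r_half_is_half(self, rng):
        z = rng.standard_normal((64, 64))
        spec = amplitude_spectrum(SurfaceMap(z, 20.0))
        rad = radial_spectrum(spec)
        r05 = r_half(spec)
        cum = np.concatenate([[0.0], np.cumsum(rad)]) / rad.sum()
        assert np.interp(r05, np.arange(cum.size), cum) == pytest.approx(0.5, abs=1e-12)

    def test_smaller_grains_give_smaller_shw(self):
        """Finer granularity moves spectral weight outward: paired seeds."""
        smaller, larger = [], []
        for seed in range(20):
            cfgs = {
                "small": SurfaceConfig(grid_size=128, grain_radius_nm=60.0, activation_level=1.0, noise_sd=0.0),
                "large": SurfaceConfig(grid_size=128, grain_radius_nm=150.0, activation_level=1.0, noise_sd=0.0),
            }
            vals = {}
            for key, cfg in cfgs.items():
                spec = amplitude_spectrum(generate_surface(cfg, seed=seed))
                radial_spectrum(spec)
                vals[key] = s_hw(spec)
            smaller.append(vals["small"])
            larger.append(vals["large"])
        assert all(s < l for s, l in zip(smaller, larger))


class TestParameterSuite:
    def test_exactly_37_named_parameters(self, small_surface_config):
        ps = parameter_suite(generate_surface(small_surface_config, seed=0))
        assert len(ps) == 37
        assert set(ps.values) == set(PARAMETER_NAMES)

    def test_constant_map_amplitude_family(self):
        ps = parameter_suite(SurfaceMap(np.full((32, 32), 4.0), 20.0))
        assert ps["Sa"] == 0.0
        assert ps["Sq"] == 0.0
        assert math.isnan(ps["Ssk"])
        assert math.isnan(ps["Sku"])

    def test_gaussian_moments(self):
        """White Gaussian maps: skewness ~ 0, kurtosis ~ 3 in the mean."""
        ssk, sku = [], []
        for seed in range(50):
            z = np.random.default_rng(seed).standard_normal((64, 64))
            ps = parameter_suite(SurfaceMap(z, 20.0))
            ssk.append(ps["Ssk"])
            sku.append(ps["Sku"])
        assert abs(np.mean(ssk)) < 0.02
        assert np.mean(sku) == pytest.approx(3.0, abs=0.05)

    def test_sq_ge_sa_and_bounds(self, small_surface_config):
        for seed in range(5):
            ps = parameter_suite(generate_surface(small_surface_config, seed=seed))
            assert ps["Sq"] >= ps["Sa"] >= 0.0
            assert 0.0 < ps["Stdi"] <= 1.0
            assert 0.0 < ps["Srwi"] <= 1.0
            assert ps["Shw"] > 0.0

    def test_spatial_params_invariant_to_shift_and_offset(self, rng):
        z = rng.standard_normal((64, 64))
        a = parameter_suite(SurfaceMap(z, 20.0))
        b = parameter_suite(SurfaceMap(np.roll(z, (7, 3), (0, 1)) + 5.0, 20.0))
        for name in ("Stdi", "Srwi", "Shw", "Srw", "Std"):
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_rotation_by_90_deg(self, small_surface_config, rng):
        """Isotropic maps keep S_tdi; anisotropic maps rotate their Std."""
        iso = rng.standard_normal((64, 64))
        a = parameter_suite(SurfaceMap(iso, 20.0))
        b = parameter_suite(SurfaceMap(np.rot90(iso).copy(), 20.0))
        assert b["Stdi"] == pytest.approx(a["Stdi"], rel=0.05)
        aniso = cosine_map(64, 8, angle=0.0)
        c = parameter_suite(aniso)
        d = parameter_suite(SurfaceMap(np.rot90(aniso.values).copy(), 20.0))
        assert abs((c["Std"] - d["Std"]) % 180.0) == pytest.approx(90.0, abs=6.0)


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    level=st.floats(0.0, 1.0),
    aniso=st.floats(0.0, 1.0),
)
def test_index_bounds_property(seed, level, aniso):
    """0 < S_tdi <= 1 and 0 < S_rwi <= 1 on every nonzero surface."""
    cfg = SurfaceConfig(
        grid_size=64,
        fold_wavelength_nm=400.0,
        activation_level=level,
        fold_anisotropy=aniso,
    )
    spec = amplitude_spectrum(generate_surface(cfg, seed=seed))
    angular_spectrum(spec)
    radial_spectrum(spec)
    assert 0.0 < s_tdi(spec) <= 1.0
    assert 0.0 < s_rwi(spec) <= 1.0
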