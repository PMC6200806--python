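import math

import numpy as np
import pytest

import phasemammo as pm
from phasemammo.constants import wavelength_m
from phasemammo.errors import InvalidInputError


class TestTalbotDistance:
    def test_pi_half_first_order_hand_value(self):
        # p1 = 4.9 um at 25 keV (lambda = 0.049594 nm): d = p1^2 / (2 lambda)
        cfg = pm.InterferometerConfig(p1=4.9, design_energy=25.0,
                                      phase_shift_type="pi_half", talbot_order=1)
        assert pm.talbot_distance(cfg) == pytest.approx(0.242067, rel=1e-4)

    def test_pi_grating_quarter_distance(self):
        half = pm.InterferometerConfig(phase_shift_type="pi_half")
        pi = pm.InterferometerConfig(phase_shift_type="pi")
        assert pm.talbot_distance(pi) == pytest.approx(
            pm.talbot_distance(half) / 4.0, rel=1e-12)

    def test_linear_in_order(self):
        d1 = pm.talbot_distance(pm.InterferometerConfig(talbot_order=1))
        d3 = pm.talbot_distance(pm.InterferometerConfig(talbot_order=3))
        assert d3 == pytest.approx(3 * d1, rel=1e-12)

    def test_design_matches_stated_geometry(self):
        # default geometry lands within 5% of the 25 cm inter-grating distance
        cfg = pm.InterferometerConfig()
        assert abs(pm.talbot_distance(cfg) - 0.25) / 0.25 < 0.05


class TestAngularSensitivity:
    def test_hand_value(self):
        cfg = pm.InterferometerConfig(inter_grating_distance=0.25, p2=5.0)
        assert pm.angular_sensitivity(cfg) == pytest.approx(
            2 * math.pi * 5e4, rel=1e-12)

    def test_linear_in_distance(self):
        c1 = pm.InterferometerConfig(inter_grating_distance=0.2)
        c2 = pm.InterferometerConfig(inter_grating_distance=0.4)
        assert pm.angular_sensitivity(c2) == pytest.approx(
            2 * pm.angular_sensitivity(c1))

    def test_flat_phase_no_fringe_shift(self):
        cfg = pm.InterferometerConfig()
        shift = pm.refraction_fringe_shift(np.full((16, 16), 3.7), 0.071,
                                           cfg, 25.0)
        np.testing.assert_allclose(shift, 0.0, atol=1e-12)

    def test_linear_phase_ramp_constant_shift(self):
        cfg = pm.InterferometerConfig()
        cols = np.arange(32, dtype=float)
        phase = np.tile(cols * 0.5, (8, 1))  # 0.5 rad per pixel
        shift = pm.refraction_fringe_shift(phase, 0.071, cfg, 25.0)
        lam = wavelength_m(25.0)
        expected = pm.angular_sensitivity(cfg) * lam / (2 * math.pi) \
            * 0.5 / 0.071e-3
        np.testing.assert_allclose(shift, expected, rtol=1e-12)


class TestSteppingStackForward:
    def test_noiseless_flat_maps_trace_cosine(self, mono_spectrum):
        cfg = pm.InterferometerConfig(n_steps=8, reference_visibility=0.5)
        maps = tuple(np.zeros((4, 4)) for _ in range(3))
        stack = pm.simulate_stepping_stack(maps, cfg, mono_spectrum, 1.0,
                                           noise=False, pixel_pitch=0.071)
        fl = mono_spectrum.total_fluence_rate * 0.071**2
        expected = (fl / 8) * (1 + 0.5 * np.cos(cfg.step_phases))
        np.testing.assert_allclose(stack.counts[:, 0, 0], expected, rtol=1e-12)

    def test_step_sum_equals_total_transmitted(self, mono_spectrum):
        # cosine sums to zero over a full period of uniform steps
        for vis in (0.2, 0.45, 0.9):
            cfg = pm.InterferometerConfig(reference_visibility=vis)
            att = np.full((3, 3), 0.7)
            stack = pm.simulate_stepping_stack(
                (att, np.zeros_like(att), np.zeros_like(att)), cfg,
                mono_spectrum, 2.0, noise=False, pixel_pitch=0.071)
            total = mono_spectrum.total_fluence_rate * 0.071**2 * 2.0
            np.testing.assert_allclose(stack.counts.sum(axis=0),
                                       total * math.exp(-0.7), rtol=1e-12)

    def test_poisson_variance_matches_mean(self, mono_spectrum):
        cfg = pm.InterferometerConfig()
        maps = tuple(np.zeros((100, 100)) for _ in range(3))
        stack = pm.simulate_stepping_stack(maps, cfg, mono_spectrum, 1e-3,
                                           seed=7, pixel_pitch=0.071)
        counts = stack.counts[0]  # one step, 10^4 iid pixels
        mean, var = counts.mean(), counts.var()
        assert var == pytest.approx(mean, rel=0.1)

    def test_reference_visibility_recovered_exactly(self, mono_spectrum):
        cfg = pm.InterferometerConfig(reference_visibility=0.45)
        maps = tuple(np.zeros((8, 8)) for _ in range(3))
        ref = pm.simulate_stepping_stack(maps, cfg, mono_spectrum, 1.0,
                                         with_sample=False, noise=False,
                                         pixel_pitch=0.071)
        assert pm.median_visibility(ref) == pytest.approx(0.45, abs=1e-12)

    def test_negative_exposure_rejected(self, mono_spectrum):
        cfg = pm.InterferometerConfig()
        maps = tuple(np.zeros((2, 2)) for _ in range(3))
        with pytest.raises(InvalidInputError):
            pm.simulate_stepping_stack(maps, cfg, mono_spectrum, -1.0,
                                       pixel_pitch=0.071)


class TestPlainRadiograph:
    def test_noiseless_uniform_and_half_attenuation(self, mono_spectrum):
        shape = (4, 4)
        fl = mono_spectrum.total_fluence_rate * 0.071**2 * 1.0
        zero = np.zeros(shape)
        img0 = pm.simulate_plain_radiograph((zero, zero, zero), mono_spectrum,
                                            1.0, noise=False, pixel_pitch=0.071)
        np.testing.assert_allclose(img0, fl, rtol=1e-12)
        att = np.full(shape, math.log(2.0))
        img1 = pm.simulate_plain_radiograph((att, zero, zero), mono_spectrum,
                                            1.0, noise=False, pixel_pitch=0.071)
        np.testing.assert_allclose(img1, fl / 2.0, rtol=1e-12)

    def test_relative_noise_scales_as_inverse_sqrt_counts(self, mono_spectrum):
        zero = np.zeros((200, 200))
        img = pm.simulate_plain_radiograph((zero, zero, zero), mono_spectrum,
                                           1e-3, seed=3, pixel_pitch=0.071)
        rel = img.std() / img.mean()
        assert rel == pytest.approx(1.0 / math.sqrt(img.mean()), rel=0.05)

    def test_multibin_reduces_to_sum_of_monochromatic(self):
        spec = pm.make_spectrum(25.0, 0.05, 1e6, 5)
        zero = np.zeros((3, 3))
        total = pm.simulate_plain_radiograph((zero, zero, zero), spec, 1.0,
                                             noise=False, pixel_pitch=0.071)
        parts = sum(
            pm.simulate_plain_radiograph(
                (zero, zero, zero),
                pm.Spectrum(np.array([e]), spec.bin_width, np.array([r])),
                1.0, noise=False, pixel_pitch=0.071)
            for e, r in zip(spec.bin_centers, spec.fluence_rate))
        np.testing.assert_allclose(total, parts, rtol=1e-12)
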