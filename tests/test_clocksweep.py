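"""Clock-sweep statistic: profile extraction, delta/mean, overlay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermibc import (
    AngularProfile,
    LesionSpec,
    OverlayAnnotation,
    generate_lesion_image,
    radial_profile,
    render_overlay,
    segment_lesion,
    sweep_statistic,
)
from dermibc.clocksweep import risk_label, statistic_label
from dermibc.segmentation import clock_angles


def profile_from(values):
    values = np.asarray(values, float)
    return AngularProfile(angles=clock_angles(len(values)), values=values)


class TestRadialProfile:
    def test_uniform_interior_gives_constant_profile(self, uniform_lesion):
        profile = radial_profile(uniform_lesion["image"], uniform_lesion["mask"])
        level = uniform_lesion["spec"].lesion_level
        assert np.abs(profile.values - level).max() < 1e-6

    def test_matches_analytic_modulation_within_one_percent(self, modulated_lesion):
        profile = modulated_lesion["profile"]
        analytic = modulated_lesion["spec"].interior_brightness(profile.angles)
        assert np.abs(profile.values / analytic - 1).max() < 0.01

    def test_clockwise_image_rotation_shifts_profile_by_90_samples(self, modulated_lesion):
        img = modulated_lesion["image"]
        profile = modulated_lesion["profile"]
        img_cw = np.rot90(img, k=-1)  # 90 deg clockwise
        profile_cw = radial_profile(img_cw, segment_lesion(img_cw))
        assert np.allclose(profile_cw.values, np.roll(profile.values, 90), rtol=5e-3)

    def test_mismatched_shapes_rejected(self, modulated_lesion):
        with pytest.raises(ValueError, match="shapes differ"):
            radial_profile(np.zeros((64, 64)), modulated_lesion["mask"])


class TestSweepStatistic:
    def test_constant_profile_has_zero_statistic(self):
        res = sweep_statistic(profile_from(np.full(360, 120.0)))
        assert res.delta == 0.0
        assert res.statistic == 0.0

    def test_sine_profile_closed_form(self):
        # m = 100 + 20 sin(theta): delta 40, mean 100, statistic 0.4
        angles = clock_angles(360)
        res = sweep_statistic(profile_from(100 + 20 * np.sin(angles)))
        assert res.delta == pytest.approx(40.0, abs=1e-3)
        assert res.mean_brightness == pytest.approx(100.0, abs=1e-9)
        assert res.statistic == pytest.approx(0.4, abs=1e-3)
        assert res.brightest_angle == pytest.approx(np.pi / 2, abs=1e-9)
        assert res.darkest_angle == pytest.approx(3 * np.pi / 2, abs=1e-9)

    def test_max_variation_at_steepest_slope(self):
        # |d/dtheta (100 + 20 sin)| peaks where cos = +-1: the 12/6 o'clock
        # samples; brute-force scan of central differences agrees
        angles = clock_angles(360)
        values = 100 + 20 * np.sin(angles)
        res = sweep_statistic(profile_from(values))
        deriv = np.abs((np.roll(values, -1) - np.roll(values, 1)) / 2)
        assert res.max_variation_angle in (0.0, pytest.approx(np.pi))
        idx = int(round(res.max_variation_angle / (2 * np.pi / 360)))
        assert deriv[idx] == pytest.approx(deriv.max(), rel=1e-12)

    def test_ties_break_toward_noon(self):
        values = np.full(360, 50.0)
        values[[10, 200]] = 80.0  # two equal maxima
        res = sweep_statistic(profile_from(values), smoothing_window=1)
        assert res.brightest_angle == pytest.approx(np.radians(10))

    def test_zero_mean_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            sweep_statistic(profile_from(np.zeros(360)))

    def test_alternative_denominator(self):
        res = sweep_statistic(profile_from(100 + 20 * np.sin(clock_angles(360))),
                              mean_intensity=200.0)
        assert res.statistic == pytest.approx(0.2, abs=1e-3)

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sweep_statistic(profile_from(np.ones(360)), smoothing_window=4)

    @given(
        base=st.floats(10.0, 200.0),
        amp=st.floats(0.0, 0.9),
        phase=st.floats(0.0, 2 * np.pi),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_statistic_nonnegative_and_zero_iff_constant(self, base, amp, phase):
        values = base * (1 + amp * np.sin(clock_angles(90) + phase))
        res = sweep_statistic(profile_from(values), smoothing_window=1)
        assert res.statistic >= 0.0
        assert (res.statistic == 0.0) == (np.ptp(values) == 0.0)


class TestEndToEndInvariances:
    @pytest.mark.parametrize("amp", [0.05, 0.1, 0.2, 0.4])
    def test_recovers_twice_amplitude_within_two_percent(self, amp):
        img, truth = generate_lesion_image(LesionSpec(angular_modulation=(amp, 0.0)))
        res = sweep_statistic(radial_profile(img, segment_lesion(img)))
        assert res.statistic == pytest.approx(truth.delta_over_mean, rel=0.02)

    def test_intensity_scaling_invariance(self, modulated_lesion):
        img = modulated_lesion["image"]
        s1 = sweep_statistic(modulated_lesion["profile"]).statistic
        scaled = img * 0.5
        s2 = sweep_statistic(radial_profile(scaled, segment_lesion(scaled))).statistic
        assert s2 == pytest.approx(s1, rel=1e-6)

    def test_rotation_invariance(self, modulated_lesion):
        img = modulated_lesion["image"]
        s1 = sweep_statistic(modulated_lesion["profile"]).statistic
        rot = np.rot90(img)
        s2 = sweep_statistic(radial_profile(rot, segment_lesion(rot))).statistic
        assert s2 == pytest.approx(s1, rel=1e-6)


class TestOverlay:
    def test_label_formats(self):
        assert statistic_label(0.29) == "0.29"
        assert risk_label(0.17) == "Risk = 0.17"
        assert statistic_label(0.29481) == "0.29"

    def test_output_shape_and_annotation_pixels(self, modulated_lesion):
        img = modulated_lesion["image"]
        mask = modulated_lesion["mask"]
        res = sweep_statistic(modulated_lesion["profile"])
        out = render_overlay(img, mask, res, OverlayAnnotation(risk_score=0.17))
        assert out.shape == (*img.shape, 3)
        # hands introduce saturated colour pixels absent from the gray base
        assert (out[..., 2].astype(int) - out[..., 0].astype(int) > 100).any()  # blue
        assert (out[..., 1].astype(int) - out[..., 0].astype(int) > 100).any()  # green
        assert (out[..., 0].astype(int) - out[..., 1].astype(int) > 100).any()  # red

    def test_risk_score_validated(self):
        with pytest.raises(ValueError, match="risk_score"):
            OverlayAnnotation(risk_score=1.3)
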