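import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crtsync.segments import build_segment_model
from crtsync.synth import SimParams, generate_patient, make_type1_truth, make_type2_truth
from crtsync.wallmotion import (
    WallMotionError,
    centroid_track,
    compute_delay_map,
    delay_recovery_error,
    exclude_akinetic,
    radial_displacement_curves,
    reference_curve,
    time_to_peak,
    xcorr_delay,
)

from conftest import circle_stack


class TestCentroid:
    def test_static_landmarks_constant_centroids(self):
        stack = circle_stack([30.0] * 4)
        cent = centroid_track(stack)
        assert np.allclose(cent, cent[0])

    def test_landmark_translation_moves_centroids_linearly(self):
        T = np.zeros((4, 2))
        T[2] = (3.0, 0.0)
        stack = circle_stack([30.0] * 4, translation=T)
        cent = centroid_track(stack)
        assert np.allclose(cent[2] - cent[0], [3.0, 0.0])
        assert np.allclose(cent[1], cent[0])

    def test_generator_translation_recovered(self):
        stack, _ = generate_patient(
            SimParams(seed=4, translation_amplitude_mm=4.0), make_type1_truth()
        )
        cent = centroid_track(stack)
        # centroid minus the landmark translation must be constant per slice
        drift = cent - stack.mitral_centre[:, None, :2]
        assert np.allclose(drift, drift[0], atol=1e-9)

    def test_missing_landmarks_rejected(self):
        stack = circle_stack([30.0] * 4)
        stack.mitral_centre[1] = np.nan
        with pytest.raises(WallMotionError):
            centroid_track(stack)


class TestDisplacement:
    def test_constant_circle_zero_curves(self):
        curves = radial_displacement_curves(circle_stack([30.0] * 5))
        assert np.allclose(curves.disp, 0.0, atol=1e-9)
        assert curves.valid.all()

    def test_shrinking_circle_uniform_displacement(self):
        curves = radial_displacement_curves(circle_stack([50.0, 50.0, 45.0]))
        assert np.allclose(curves.disp[:, :, 2], 5.0, atol=1e-2)
        assert np.allclose(curves.disp[:, :, 0], 0.0, atol=1e-9)

    def test_rigid_translation_cancelled_by_landmark_correction(self):
        rng = np.random.default_rng(0)
        T = rng.normal(0, 2.0, size=(6, 2))
        T[0] = 0
        static = radial_displacement_curves(circle_stack([30.0] * 6))
        moved = radial_displacement_curves(circle_stack([30.0] * 6, translation=T))
        assert np.allclose(moved.disp, static.disp, atol=1e-9)

    def test_centroid_outside_contour_flagged(self):
        # offset the landmarks far from the contours so the axis misses them
        stack = circle_stack([20.0] * 3)
        stack.mitral_centre[:, 0] += 80.0
        stack.apex[:, 0] += 80.0
        curves = radial_displacement_curves(stack)
        assert not curves.valid.any()

    def test_resampling_interpolates_off_grid_points(self):
        # rendered boundary points rotated half a sample off the analysis grid
        truth = make_type1_truth()
        stack, truth = generate_patient(
            SimParams(seed=13, point_angle_offset_deg=1.8), truth
        )
        dm = compute_delay_map(radial_displacement_curves(stack))
        err = delay_recovery_error(dm.delay_ms[dm.valid], truth.site_delay_ms[dm.valid])
        assert err <= stack.frame_interval_ms / 2


class TestXcorr:
    def test_identical_curves_zero_delay_unit_corr(self):
        t = np.arange(30) * 33.0
        ref = np.sin(np.pi * np.clip(t, 0, 500) / 500) ** 2
        d, c = xcorr_delay(ref, ref, 33.0)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_two_frame_shift_is_66_ms(self):
        t = np.arange(30) * 33.0
        ref = np.exp(-0.5 * ((t - 400) / 120.0) ** 2)
        curve = np.exp(-0.5 * ((t - 400 - 66.0) / 120.0) ** 2)
        d, c = xcorr_delay(curve, ref, 33.0)
        assert d == pytest.approx(66.0, abs=1e-6)
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_subframe_shift_recovered_within_5_ms(self):
        t = np.arange(30) * 33.0
        ref = np.exp(-0.5 * ((t - 400) / 120.0) ** 2)
        curve = np.exp(-0.5 * ((t - 400 - 45.0) / 120.0) ** 2)
        d, _ = xcorr_delay(curve, ref, 33.0)
        assert d == pytest.approx(45.0, abs=5.0)

    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(-120, 120), width=st.floats(80, 160))
    def test_antisymmetry(self, shift, width):
        t = np.arange(30) * 33.0
        a = np.exp(-0.5 * ((t - 450) / width) ** 2)
        b = np.exp(-0.5 * ((t - 450 - shift) / width) ** 2)
        dab, _ = xcorr_delay(a, b, 33.0)
        dba, _ = xcorr_delay(b, a, 33.0)
        assert dab == pytest.approx(-dba, abs=8.0)

    def test_constant_curve_rejected(self):
        ref = np.sin(np.arange(30) / 5.0)
        with pytest.raises(WallMotionError):
            xcorr_delay(np.ones(30), ref, 33.0)


class TestTimeToPeak:
    def test_single_peak(self):
        y = np.zeros(20)
        y[12] = 5.0
        y[11] = y[13] = 2.0
        assert time_to_peak(y, 33.0) == pytest.approx(396.0)

    def test_flash_takes_initial_peak(self):
        t = np.arange(30) * 33.0
        y = 2.0 * np.exp(-0.5 * ((t - 60) / 30.0) ** 2) + 6.0 * np.exp(
            -0.5 * ((t - 500) / 100.0) ** 2
        )
        assert time_to_peak(y, 33.0, first_peak=True) == pytest.approx(60.0, abs=20.0)
        assert time_to_peak(y, 33.0) == pytest.approx(500.0, abs=20.0)

    def test_monotone_curve_returns_last_frame(self):
        y = np.linspace(0, 5, 20)
        assert time_to_peak(y, 33.0) == pytest.approx(19 * 33.0)


class TestReference:
    def test_identical_curves_reference_equals_curve(self):
        curves = radial_displacement_curves(circle_stack([40.0, 38.0, 36.0, 37.0]))
        ref = reference_curve(curves)
        assert np.allclose(ref, curves.disp[0, 0], atol=1e-2)

    def test_mirror_perturbations_cancel(self, clean_type2_analysis):
        _, _, curves, _ = clean_type2_analysis
        ref = reference_curve(curves)
        import copy

        pert = copy.deepcopy(curves)
        e = np.sin(np.arange(curves.n_frames) / 3.0)
        pert.disp[0, 0] += e
        pert.disp[0, 1] -= e
        assert np.allclose(reference_curve(pert), ref, atol=1e-9)

    def test_reference_peak_within_site_peak_range(self, clean_type2_analysis):
        _, _, curves, _ = clean_type2_analysis
        ref = reference_curve(curves)
        peaks = curves.disp[curves.valid].argmax(axis=1)
        assert peaks.min() <= ref.argmax() <= peaks.max()


class TestDelayMapProperties:
    def test_noise_free_delay_recovery_within_half_frame(self, clean_type2_analysis):
        stack, truth, _, dm = clean_type2_analysis
        err = delay_recovery_error(dm.delay_ms[dm.valid], truth.site_delay_ms[dm.valid])
        assert err <= stack.frame_interval_ms / 2

    def test_translation_invariance_within_1_ms(self):
        truth = make_type2_truth(flash=False)
        base, _ = generate_patient(SimParams(seed=21), truth)
        moved, _ = generate_patient(
            SimParams(seed=21, translation_amplitude_mm=5.0), truth
        )
        dm0 = compute_delay_map(radial_displacement_curves(base))
        dm1 = compute_delay_map(radial_displacement_curves(moved))
        both = dm0.valid & dm1.valid
        assert both.sum() > 800
        assert np.nanmax(np.abs(dm0.delay_ms[both] - dm1.delay_ms[both])) < 1.0


class TestExcludeAkinetic:
    def test_scarred_segment_sites_invalid(self, model9):
        truth = make_type2_truth(scar_segments={5: 0.8}, flash=False)
        stack, truth = generate_patient(SimParams(seed=22), truth)
        curves = radial_displacement_curves(stack)
        dm = compute_delay_map(curves)
        dm2 = exclude_akinetic(curves, dm, model9, truth.scar_segments)
        segs = dm2.site_segments(model9)
        assert not dm2.valid[segs == 5].any()
        # vigorous unscarred sites stay valid
        assert dm2.valid[segs == 1].mean() > 0.9

    def test_passive_low_amplitude_site_excluded(self, model9):
        # full transmurality => amplitude multiplier 0 => below 2 mm threshold
        truth = make_type2_truth(scar_segments={11: 1.0}, flash=False)
        stack, truth = generate_patient(SimParams(seed=23), truth)
        curves = radial_displacement_curves(stack)
        dm = compute_delay_map(curves)
        dm2 = exclude_akinetic(curves, dm, model9, scar=None)  # amplitude rule only
        segs = dm2.site_segments(model9)
        core_11 = (segs == 11) & (np.abs((dm2.angles_deg[None, :] + 30) % 360 - 180) < 20)
        assert not dm2.valid[core_11].any()

    def test_everything_excluded_raises(self):
        # static circles: every site is zero-variance, nothing analyzable
        stack = circle_stack([30.0] * 6, n_slices=3)
        curves = radial_displacement_curves(stack)
        dmap = compute_delay_map(curves)
        with pytest.raises(WallMotionError):
            exclude_akinetic(curves, dmap, build_segment_model(3), None)
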