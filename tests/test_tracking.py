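import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselmotion.flow import FlowParams
from vesselmotion.io import ImageSeries, RoiMask
from vesselmotion.tracking import (
    Trajectory,
    barycenter,
    bolus_trigger,
    displacement,
    dose_arithmetic,
    enhancement_curve,
    roi_mean_hu,
    track_corrected,
    track_manual,
)


class TestBarycenter:
    def test_single_pixel(self):
        assert barycenter(RoiMask(pixels=[(3, 4)])) == (3.0, 4.0)

    def test_square_corners(self):
        mask = RoiMask(pixels=[(0, 0), (0, 2), (2, 0), (2, 2)])
        assert barycenter(mask) == (1.0, 1.0)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(5)
        pix = np.unique(rng.integers(0, 30, size=(25, 2)), axis=0)
        mask = RoiMask(pixels=pix)
        a, b = barycenter(mask)
        assert a == pytest.approx(sum(p[0] for p in pix) / len(pix), abs=1e-12)
        assert b == pytest.approx(sum(p[1] for p in pix) / len(pix), abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(
        shift=st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
        seed=st.integers(0, 2**16),
    )
    def test_translation_equivariance_exact(self, shift, seed):
        rng = np.random.default_rng(seed)
        pix = np.unique(rng.integers(100, 150, size=(12, 2)), axis=0)
        base = barycenter(RoiMask(pixels=pix))
        moved = barycenter(RoiMask(pixels=pix + np.array(shift)))
        # exact up to one ulp of the double-precision coordinate mean
        assert moved[0] == pytest.approx(base[0] + shift[0], abs=1e-12)
        assert moved[1] == pytest.approx(base[1] + shift[1], abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            barycenter(RoiMask(pixels=np.empty((0, 2))))


class TestDisplacement:
    def test_zero(self):
        delta, mag = displacement((2.5, 7.0), (2.5, 7.0))
        assert delta == (0.0, 0.0) and mag == 0.0

    def test_three_four_five(self):
        delta, mag = displacement((1.0, 1.0), (4.0, 5.0))
        assert delta == (3.0, 4.0) and mag == 5.0

    def test_physical_magnitude(self):
        # 5 px at 0.82 mm/pixel -> 4.1 mm
        _, mag = displacement((0.0, 0.0), (3.0, 4.0))
        assert mag * 0.82 == pytest.approx(4.1)

    def test_antisymmetry(self):
        d12, _ = displacement((1.0, 2.0), (5.5, -3.0))
        d21, _ = displacement((5.5, -3.0), (1.0, 2.0))
        assert d12 == (-d21[0], -d21[1])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            displacement((np.nan, 0.0), (1.0, 1.0))


class TestTrajectory:
    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**16), n=st.integers(2, 12))
    def test_telescoping(self, seed, n):
        rng = np.random.default_rng(seed)
        traj = Trajectory(rng.normal(50, 10, size=(n, 2)))
        total = traj.displacements.sum(axis=0)
        np.testing.assert_allclose(
            total, traj.barycenters[-1] - traj.barycenters[0], atol=1e-9
        )

    def test_displacements_equal_barycenter_differences_exactly(self):
        b = np.array([[1.0, 2.0], [3.5, -1.0], [4.0, 4.0]])
        traj = Trajectory(b)
        assert np.array_equal(traj.displacements, np.diff(b, axis=0))

    def test_mm_conversion(self):
        traj = Trajectory(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert traj.to_mm(0.82).step_magnitudes[0] == pytest.approx(0.82)


class TestTrackManual:
    def _series(self, n, shape=(32, 32)):
        return ImageSeries(
            frames=np.zeros((n,) + shape), pixel_spacing=0.82, interscan_time=3.0
        )

    def test_identical_masks_zero_displacement(self):
        pix = [(10, 10), (10, 11), (11, 10)]
        masks = [RoiMask(pixels=pix, frame_index=i) for i in range(4)]
        traj = track_manual(self._series(4), masks)
        assert np.all(traj.displacements == 0.0)

    def test_rigid_shift_one_row_per_frame_exact(self):
        pix = np.array([(10, 10), (10, 11), (12, 13), (11, 10)])
        masks = [RoiMask(pixels=pix + [i, 0], frame_index=i) for i in range(5)]
        traj = track_manual(self._series(5), masks)
        assert np.all(traj.displacements == np.array([1.0, 0.0]))

    def test_sinusoidal_phantom_barycenters_track_truth(self, suite):
        series, truth = suite["moderate_respiration"]
        traj = track_manual(series, truth.masks)
        rms = np.sqrt(np.mean((traj.barycenters - truth.trajectory_px) ** 2))
        assert rms <= 0.5

    def test_missing_mask_names_frame(self):
        masks = [RoiMask(pixels=[(1, 1)]), None, RoiMask(pixels=[(1, 1)])]
        with pytest.raises(ValueError, match="frame 1"):
            track_manual(self._series(3), masks)


class TestRoiMeanHu:
    def test_uniform_frame(self):
        frame = np.full((8, 8), 100.0)
        assert roi_mean_hu(frame, RoiMask(pixels=[(1, 1), (2, 2)])) == 100.0

    def test_balanced_half_and_half(self):
        frame = np.zeros((8, 8))
        frame[4:] = 200.0
        roi = RoiMask(pixels=[(0, 0), (1, 1), (4, 4), (5, 5)])
        assert roi_mean_hu(frame, roi) == 100.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        frame = rng.normal(50, 40, size=(12, 12))
        pix = np.unique(rng.integers(0, 12, size=(9, 2)), axis=0)
        roi = RoiMask(pixels=pix)
        expected = sum(frame[tuple(p)] for p in pix) / len(pix)
        assert roi_mean_hu(frame, roi) == pytest.approx(expected, abs=1e-12)


class TestBolusTrigger:
    def test_threshold_reached(self):
        assert bolus_trigger([40, 80, 129, 135], threshold=130) == 3

    def test_first_element_at_threshold(self):
        assert bolus_trigger([130, 200], threshold=130) == 0

    def test_never_reached(self):
        assert bolus_trigger([40, 80, 100], threshold=130) is None

    @settings(deadline=None, max_examples=40)
    @given(
        seed=st.integers(0, 2**16),
        t1=st.floats(50, 200),
        t2=st.floats(50, 200),
    )
    def test_monotone_in_threshold(self, seed, t1, t2):
        rng = np.random.default_rng(seed)
        means = rng.uniform(0, 260, size=10)
        lo, hi = min(t1, t2), max(t1, t2)
        first_lo = bolus_trigger(means, lo)
        first_hi = bolus_trigger(means, hi)
        if first_hi is not None:
            assert first_lo is not None and first_lo <= first_hi


class TestTrackCorrected:
    def test_static_phantom_keeps_roi(self, static_phantom):
        series, truth = static_phantom
        masks, _ = track_corrected(series, truth.masks[0])
        for m in masks:
            np.testing.assert_array_equal(m.pixels, truth.masks[0].pixels)

    def test_drift_phantom_tracks_vessel(self, small_drift_phantom):
        series, truth = small_drift_phantom
        masks, traj = track_corrected(series, truth.masks[0])
        # corrected ROI stays on the vessel: IoU >= 0.8 on every frame
        for m, tm in zip(masks, truth.masks):
            a = {tuple(p) for p in m.pixels}
            b = {tuple(p) for p in tm.pixels}
            assert len(a & b) / len(a | b) >= 0.8
        # per-step displacement error <= 1 px
        err = np.abs(traj.displacements - truth.displacement_px)
        assert err.max() <= 1.0

    def test_corrected_enhancement_tracks_truth(self, small_drift_phantom):
        series, truth = small_drift_phantom
        masks, _ = track_corrected(series, truth.masks[0])
        curve = enhancement_curve(series, masks)
        np.testing.assert_allclose(
            curve.roi_mean_hu, truth.enhancement_true, rtol=0.05
        )

    def test_roi_pushed_out_of_bounds_names_frame(self, monkeypatch, static_phantom):
        import vesselmotion.tracking as tracking

        series, truth = static_phantom
        monkeypatch.setattr(
            tracking, "roi_displacement", lambda mvf, roi, reduction: (500.0, 0.0, 500.0)
        )
        with pytest.raises(ValueError, match="frame 1"):
            track_corrected(series, truth.masks[0], FlowParams(n_iterations=1))

    def test_area_invariant_under_correction(self, small_drift_phantom):
        series, truth = small_drift_phantom
        masks, _ = track_corrected(series, truth.masks[0])
        areas = {len(m) for m in masks}
        assert areas == {len(truth.masks[0])}


class TestDoseArithmetic:
    def test_protocol_values(self):
        mas, cumulative = dose_arithmetic(40.0, 0.6, 2.81, 5)
        assert mas == pytest.approx(24.0)
        assert cumulative == pytest.approx(14.05)

    def test_identity_factors(self):
        mas, cumulative = dose_arithmetic(1.0, 7.3, 2.5, 1)
        assert mas == 7.3 and cumulative == 2.5

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            dose_arithmetic(0.0, 0.6, 2.81, 5)
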