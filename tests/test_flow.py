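import numpy as np
import pytest

from vesselmotion.flow import (
    FlowParams,
    MotionVectorField,
    UnitsError,
    horn_schunck,
    roi_displacement,
    to_physical,
    to_velocity,
    total_movement,
)
from vesselmotion.io import RoiMask

from conftest import gaussian_blob


class TestExactZeros:
    def test_identical_frames_give_exact_zero_field(self):
        rng = np.random.default_rng(0)
        f = rng.normal(40, 30, size=(20, 20))
        mvf = horn_schunck(f, f, FlowParams())
        assert np.all(mvf.ap == 0.0)
        assert np.all(mvf.lat == 0.0)

    def test_uniform_frames_give_exact_zero_field(self):
        # no spatial gradient: the update term vanishes even though HU changes
        f0 = np.full((12, 12), 50.0)
        f1 = np.full((12, 12), 180.0)
        mvf = horn_schunck(f0, f1, FlowParams())
        assert np.all(mvf.ap == 0.0)
        assert np.all(mvf.lat == 0.0)


class TestTranslationRecovery:
    def test_one_pixel_shift_recovered(self):
        f0 = gaussian_blob((32.0, 32.0))
        f1 = gaussian_blob((33.0, 32.0))
        mvf = horn_schunck(f0, f1, FlowParams(alpha=5, n_iterations=100))
        support = f0 >= f0.max() / 2
        assert mvf.ap[support].mean() == pytest.approx(1.0, abs=0.25)
        assert mvf.lat[support].mean() == pytest.approx(0.0, abs=0.25)

    def test_subpixel_shift_recovered(self):
        f0 = gaussian_blob((32.0, 32.0))
        f1 = gaussian_blob((32.3, 32.0))
        mvf = horn_schunck(f0, f1, FlowParams())
        support = f0 >= f0.max() / 2
        assert mvf.ap[support].mean() == pytest.approx(0.3, abs=0.15)

    def test_approximate_antisymmetry(self):
        f0 = gaussian_blob((30.0, 30.0))
        f1 = gaussian_blob((30.8, 30.0))
        fwd = horn_schunck(f0, f1, FlowParams())
        bwd = horn_schunck(f1, f0, FlowParams())
        support = f0 >= f0.max() / 2
        fwd_mean = fwd.ap[support].mean()
        bwd_mean = bwd.ap[support].mean()
        assert abs(fwd_mean + bwd_mean) <= 0.1 * abs(fwd_mean)

    def test_interior_translation_equivariance(self):
        f0 = gaussian_blob((28.0, 28.0), shape=(64, 64))
        f1 = gaussian_blob((29.0, 28.0), shape=(64, 64))
        base = horn_schunck(f0, f1, FlowParams(n_iterations=40))
        shifted = horn_schunck(
            np.roll(f0, (3, 2), axis=(0, 1)),
            np.roll(f1, (3, 2), axis=(0, 1)),
            FlowParams(n_iterations=40),
        )
        interior = np.s_[8:-8, 8:-8]
        np.testing.assert_allclose(
            shifted.ap[8 + 3 : -8 + 3, 8 + 2 : -8 + 2], base.ap[interior], atol=1e-6
        )

    def test_flow_smoothness_grows_with_alpha(self):
        f0 = gaussian_blob((30.0, 30.0))
        f1 = gaussian_blob((31.0, 30.0))
        support = f0 >= f0.max() / 2
        sds = []
        for alpha in (5.0, 50.0, 500.0, 5000.0):
            mvf = horn_schunck(f0, f1, FlowParams(alpha=alpha))
            sds.append(mvf.ap[support].std())
        # at the fixed 100-iteration budget the flattening is monotone from
        # alpha = 50 upward; alpha = 5 -> 50 mostly rescales the magnitude
        assert sds[1] > sds[2] > sds[3]
        assert sds[3] < 0.01 * sds[0]

    def test_deterministic(self):
        f0 = gaussian_blob((30.0, 30.0))
        f1 = gaussian_blob((30.5, 30.5))
        a = horn_schunck(f0, f1, FlowParams())
        b = horn_schunck(f0, f1, FlowParams())
        assert np.array_equal(a.ap, b.ap) and np.array_equal(a.lat, b.lat)


class TestValidation:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            horn_schunck(np.zeros((8, 8)), np.zeros((8, 9)))

    def test_non_finite_rejected(self):
        f = np.zeros((8, 8))
        g = f.copy()
        g[3, 3] = np.nan
        with pytest.raises(ValueError):
            horn_schunck(f, g)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            horn_schunck(np.zeros((2, 5)), np.zeros((2, 5)))

    @pytest.mark.parametrize("kwargs", [{"alpha": 0}, {"n_iterations": 0}, {"averaging_kernel": "bogus"}])
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FlowParams(**kwargs)


class TestTotalMovement:
    def test_three_four_five(self):
        mvf = MotionVectorField(ap=np.full((4, 4), 3.0), lat=np.full((4, 4), 4.0))
        assert np.all(total_movement(mvf) == 5.0)

    def test_zero_field(self):
        mvf = MotionVectorField(ap=np.zeros((4, 4)), lat=np.zeros((4, 4)))
        assert np.all(total_movement(mvf) == 0.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(7)
        ap, lat = rng.normal(size=(2, 16, 16))
        mvf = MotionVectorField(ap=ap, lat=lat)
        mag = total_movement(mvf)
        for i in range(16):
            for j in range(16):
                assert mag[i, j] == pytest.approx(
                    (ap[i, j] ** 2 + lat[i, j] ** 2) ** 0.5, abs=1e-12
                )


class TestUnitConversions:
    def test_pixel_to_mm_to_velocity(self):
        mvf = MotionVectorField(ap=np.ones((4, 4)), lat=np.zeros((4, 4)))
        mm = to_physical(mvf, 0.82)
        assert np.all(mm.ap == pytest.approx(0.82)) and mm.units_state == "mm"
        # 6 mm over the 3 s interscan interval -> 2 mm/s
        six = MotionVectorField(ap=np.full((4, 4), 6.0), lat=np.zeros((4, 4)), units_state="mm")
        vel = to_velocity(six, 3.0)
        assert np.all(vel.ap == pytest.approx(2.0)) and vel.units_state == "mm_per_s"

    def test_wrong_units_state_rejected(self):
        mvf = MotionVectorField(ap=np.ones((4, 4)), lat=np.zeros((4, 4)))
        with pytest.raises(UnitsError):
            to_velocity(mvf, 3.0)  # still in pixels
        mm = to_physical(mvf, 0.82)
        with pytest.raises(UnitsError):
            to_physical(mm, 0.82)  # already mm

    def test_zero_field_stays_zero(self):
        mvf = MotionVectorField(ap=np.zeros((4, 4)), lat=np.zeros((4, 4)))
        vel = to_velocity(to_physical(mvf, 0.82), 3.0)
        assert np.all(vel.ap == 0.0) and np.all(vel.lat == 0.0)


class TestRoiDisplacement:
    def test_constant_field(self):
        mvf = MotionVectorField(ap=np.full((8, 8), 2.0), lat=np.zeros((8, 8)))
        roi = RoiMask(pixels=[(2, 2), (3, 4), (5, 5)], frame_shape=(8, 8))
        assert roi_displacement(mvf, roi) == pytest.approx((2.0, 0.0, 2.0))

    def test_antisymmetric_field_cancels(self):
        ap = np.zeros((8, 8))
        ap[2, 2], ap[5, 5] = 1.5, -1.5
        mvf = MotionVectorField(ap=ap, lat=np.zeros((8, 8)))
        roi = RoiMask(pixels=[(2, 2), (5, 5)], frame_shape=(8, 8))
        ap_m, lat_m, mov = roi_displacement(mvf, roi)
        assert (ap_m, lat_m, mov) == (0.0, 0.0, 0.0)
        # mean-of-norms does not cancel
        _, _, mov2 = roi_displacement(mvf, roi, reduction="mean-of-norms")
        assert mov2 == pytest.approx(1.5)

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(11)
        mvf = MotionVectorField(ap=rng.normal(size=(10, 10)), lat=rng.normal(size=(10, 10)))
        pix = [(int(r), int(c)) for r, c in rng.integers(0, 10, size=(12, 2))]
        roi = RoiMask(pixels=pix, frame_shape=(10, 10))
        ap_m, lat_m, _ = roi_displacement(mvf, roi)
        uniq = {tuple(p) for p in roi.pixels}
        assert ap_m == pytest.approx(sum(mvf.ap[p] for p in uniq) / len(uniq), abs=1e-12)
        assert lat_m == pytest.approx(sum(mvf.lat[p] for p in uniq) / len(uniq), abs=1e-12)

    def test_empty_roi_rejected(self):
        mvf = MotionVectorField(ap=np.zeros((8, 8)), lat=np.zeros((8, 8)))
        with pytest.raises(ValueError):
            roi_displacement(mvf, RoiMask(pixels=np.empty((0, 2))))
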