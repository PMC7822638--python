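"""Registration, elliptical masking and rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cinempca.core import (
    CinempcaError,
    CineTensor,
    DegenerateLandmarksError,
    LandmarkSet,
    NotAnEllipseError,
)
from cinempca.preprocess import (
    EllipseMask,
    SimilarityTransform,
    apply_mask,
    ellipse_from_landmarks,
    fit_similarity,
    pixel_spacing_mm,
    registration_qa,
    rescale,
    warp_sequence,
)

TRI = np.array([[10.0, 20.0], [42.0, 25.0], [30.0, 55.0]])


def _cine(vox, spacing=1.0):
    return CineTensor(vox, pixel_spacing=spacing)


class TestFitSimilarity:
    def test_identity(self):
        t = fit_similarity(LandmarkSet(TRI), LandmarkSet(TRI))
        assert t.residual == pytest.approx(0.0, abs=1e-12)
        assert t.rotation == pytest.approx(0.0, abs=1e-9)
        assert t.scale == pytest.approx(1.0, abs=1e-12)
        assert not t.reflect

    def test_pure_rotation_about_centre(self):
        centre = np.array([32.0, 32.0])
        rot = SimilarityTransform(rotation=90.0)
        moved = rot.apply(TRI - centre) + centre
        t = fit_similarity(LandmarkSet(TRI), LandmarkSet(moved))
        assert t.rotation == pytest.approx(90.0, abs=1e-6)
        assert t.scale == pytest.approx(1.0, abs=1e-9)
        assert t.residual < 1e-9
        assert not t.reflect

    def test_mirror_detected(self):
        mirrored = TRI.copy()
        mirrored[:, 0] = 64.0 - mirrored[:, 0]
        t = fit_similarity(LandmarkSet(TRI), LandmarkSet(mirrored))
        assert t.reflect
        assert t.residual < 1e-9

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateLandmarksError):
            LandmarkSet(np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        rot=st.floats(-180, 180),
        scale=st.floats(0.3, 3.0),
        tx=st.floats(-30, 30),
        ty=st.floats(-30, 30),
        reflect=st.booleans(),
    )
    def test_exact_recovery_within_family(self, rot, scale, tx, ty, reflect):
        """Any similarity transform (including reflections) is recovered
        exactly from its own noise-free landmark images."""
        t = SimilarityTransform(rotation=rot, scale=scale, translation=(tx, ty), reflect=reflect)
        moved = t.apply(TRI)
        fit = fit_similarity(LandmarkSet(TRI), LandmarkSet(moved))
        assert fit.residual < 1e-6
        assert np.abs(fit.apply(TRI) - moved).max() < 1e-6
        assert fit.reflect == reflect


class TestTransformAlgebra:
    def test_inverse_round_trip(self):
        t = SimilarityTransform(rotation=33.0, scale=1.7, translation=(4.0, -2.0), reflect=True)
        pts = np.random.default_rng(0).uniform(0, 60, (10, 2))
        back = t.inverse().apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_compose(self):
        a = SimilarityTransform(rotation=20.0, scale=1.2, translation=(1.0, 2.0))
        b = SimilarityTransform(rotation=-50.0, scale=0.8, translation=(-3.0, 0.5), reflect=True)
        pts = TRI
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)))


class TestWarp:
    def test_identity_exact_at_grid_points(self):
        rng = np.random.default_rng(1)
        seq = _cine(rng.uniform(size=(16, 16, 3)))
        out = warp_sequence(seq, SimilarityTransform())
        assert np.abs(out.voxels - seq.voxels).max() < 1e-12
        assert out.frame_of_reference == "registered"

    def test_round_trip_on_smooth_image(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        blob = np.exp(-((xx - 30) ** 2 + (yy - 34) ** 2) / 120.0)
        seq = _cine(np.repeat(blob[:, :, None], 2, axis=2))
        t = SimilarityTransform(rotation=17.0, scale=1.05, translation=(2.5, -1.5))
        back = warp_sequence(warp_sequence(seq, t), t.inverse())
        inner = np.abs(back.voxels - seq.voxels)[8:-8, 8:-8, :]
        assert inner.mean() < 0.01  # documented bilinear round-trip tolerance

    def test_constant_image_constant_inside_field(self):
        seq = _cine(np.full((20, 20, 2), 3.5))
        t = SimilarityTransform(translation=(4.0, 0.0))
        out = warp_sequence(seq, t)
        assert np.allclose(out.voxels[:, 5:, :], 3.5)
        assert np.allclose(out.voxels[:, :3, :], 0.0)  # out-of-field is zero


class TestRegistrationQA:
    def test_identical_sets(self):
        qa = registration_qa(LandmarkSet(TRI), LandmarkSet(TRI))
        assert np.all(qa.residuals == 0) and qa.max_residual == 0 and not qa.flagged

    def test_three_four_five(self):
        moved = TRI.copy()
        moved[1] += [3.0, 4.0]
        qa = registration_qa(LandmarkSet(moved), LandmarkSet(TRI))
        assert qa.residuals[1] == pytest.approx(5.0, abs=1e-12)
        assert qa.max_residual == pytest.approx(5.0, abs=1e-12)

    def test_flagging_and_mismatch(self):
        moved = TRI + np.array([30.0, 0.0])
        assert registration_qa(LandmarkSet(moved), LandmarkSet(TRI), threshold=20.0).flagged
        with pytest.raises(CinempcaError):
            registration_qa(TRI, TRI[:2])


def _on_ellipse(a, b, cx, cy, angles_deg):
    th = np.deg2rad(angles_deg)
    return np.column_stack([cx + a * np.cos(th), cy + b * np.sin(th)])


class TestEllipse:
    def test_circle_recovered(self):
        pts = _on_ellipse(1.0, 1.0, 0.0, 0.0, [0, 70, 140, 215, 300])
        m = ellipse_from_landmarks(LandmarkSet(pts, role="boundary5"))
        assert np.abs(m.evaluate(pts)).max() < 1e-9
        assert m.semi_axes == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_four_three_ellipse(self):
        pts = _on_ellipse(4.0, 3.0, 0.0, 0.0, [12, 81, 155, 210, 305])
        m = ellipse_from_landmarks(LandmarkSet(pts, role="boundary5"))
        assert m.semi_axes == pytest.approx([4.0, 3.0], abs=1e-6)
        assert m.center == pytest.approx([0.0, 0.0], abs=1e-6)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0) + 1.0])
        with pytest.raises(NotAnEllipseError):
            ellipse_from_landmarks(LandmarkSet(pts, role="boundary5"))

    def test_hyperbola_rejected(self):
        th = np.array([0.2, 0.5, 0.9, -0.3, -0.8])
        pts = np.column_stack([2 * np.cosh(th), 1.5 * np.sinh(th)])
        with pytest.raises(NotAnEllipseError):
            ellipse_from_landmarks(LandmarkSet(pts, role="boundary5"))

    def test_large_variant_strictly_contains_small(self):
        pts = _on_ellipse(10.0, 6.0, 16.0, 14.0, [5, 77, 160, 228, 310])
        small = ellipse_from_landmarks(LandmarkSet(pts, role="boundary5"))
        large = small.dilated(1.5)
        assert large.variant == "large"
        assert np.all(large.evaluate(pts) < 0)  # boundary of small inside large
        assert large.semi_axes == pytest.approx(1.5 * small.semi_axes, rel=1e-9)


class TestMask:
    def _mask(self):
        pts = _on_ellipse(8.0, 5.0, 15.0, 16.0, [3, 71, 149, 222, 291])
        return ellipse_from_landmarks(LandmarkSet(pts, role="boundary5"))

    def test_whole_field_mask_is_identity(self):
        big = EllipseMask(np.array([1.0, 0.0, 1.0, -30.0, -30.0, -1e6]))
        seq = _cine(np.random.default_rng(0).uniform(size=(32, 32, 2)))
        assert np.array_equal(apply_mask(seq, big).voxels, seq.voxels)

    def test_frame_sum_equals_raster_area(self):
        m = self._mask()
        seq = _cine(np.ones((32, 32, 3)))
        out = apply_mask(seq, m)
        area = m.raster((32, 32)).sum()
        assert np.allclose(out.voxels.sum(axis=(0, 1)), area)

    def test_idempotent_and_zero_outside(self):
        m = self._mask()
        seq = _cine(np.random.default_rng(1).uniform(size=(32, 32, 2)))
        once = apply_mask(seq, m)
        twice = apply_mask(once, m)
        assert np.array_equal(once.voxels, twice.voxels)
        assert np.all(once.voxels[~m.raster((32, 32))] == 0)


class TestRescale:
    def test_spacing_from_480mm_fov(self):
        seq = _cine(np.zeros((512, 512, 2)), spacing=pixel_spacing_mm(512))
        assert rescale(seq, 64).pixel_spacing == pytest.approx(7.50)
        assert rescale(seq, 32).pixel_spacing == pytest.approx(15.0)
        assert rescale(seq, 128).pixel_spacing == pytest.approx(3.75)

    def test_constant_image_preserved(self):
        seq = _cine(np.full((128, 128, 3), 2.25))
        for target in (32, 64, 128):
            assert np.allclose(rescale(seq, target).voxels, 2.25)

    def test_checkerboard_block_average(self):
        yy, xx = np.mgrid[0:512, 0:512]
        board = (((xx // 2) + (yy // 2)) % 2).astype(float)  # period-4 checkerboard
        seq = _cine(np.repeat(board[:, :, None], 2, axis=2))
        out = rescale(seq, 128)  # 4x4 blocks each average to 0.5
        assert np.allclose(out.voxels, 0.5)

    def test_two_step_equals_direct_for_divisor_chain(self):
        rng = np.random.default_rng(2)
        seq = _cine(rng.uniform(size=(512, 512, 2)))
        via = rescale(rescale(seq, 128), 64)
        direct = rescale(seq, 64)
        assert np.allclose(via.voxels, direct.voxels, atol=1e-12)

    def test_invalid_requests(self):
        seq = _cine(np.zeros((64, 64, 2)))
        with pytest.raises(CinempcaError):
            rescale(seq, 128)  # upsampling
        with pytest.raises(CinempcaError):
            rescale(seq, 48)  # not an allowed grid
        with pytest.raises(CinempcaError):
            rescale(_cine(np.zeros((64, 32, 2))), 32)  # non-square
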