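"""Face preprocessing: grayscale, detection, landmarks, alignment, sections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sensefuse import faceprep as fp
from sensefuse.schematic import render_composite, render_face


class TestToGrayscale:
    def test_white_and_black_are_channel_invariant(self):
        white = fp.to_grayscale(fp.RawFrame(np.full((4, 4, 3), 255.0)))
        black = fp.to_grayscale(fp.RawFrame(np.zeros((4, 4, 3))))
        np.testing.assert_allclose(white.pixels, 255.0)
        np.testing.assert_allclose(black.pixels, 0.0)

    def test_bt601_weights(self):
        frame = fp.RawFrame(np.tile([100.0, 150.0, 200.0], (2, 2, 1)))
        gray = fp.to_grayscale(frame)
        expected = 0.299 * 100 + 0.587 * 150 + 0.114 * 200  # 140.75
        np.testing.assert_allclose(gray.pixels, expected)

    def test_gray_passthrough_and_bad_channels(self):
        g = fp.RawFrame(np.zeros((3, 3)))
        assert fp.to_grayscale(g) is g
        with pytest.raises(fp.FormatError):
            fp.to_grayscale(fp.RawFrame(np.zeros((3, 3, 2))))


class TestDetectFaces:
    def test_uniform_image_has_no_detections(self, detector):
        assert fp.detect_faces(fp.RawFrame(np.full((160, 160), 128.0)), detector) == []

    def test_fixture_face_detected_exactly_once(self, detector, fixture_face):
        dets = fp.detect_faces(fp.RawFrame(fixture_face.image), detector)
        assert len(dets) == 1
        x0, y0, x1, y1 = dets[0].bbox
        cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
        assert abs(cx - fixture_face.center[0]) < 15
        assert abs(cy - fixture_face.center[1]) < 15

    def test_photo_like_fixture_detected(self, detector, photo_like_face):
        assert len(fp.detect_faces(fp.RawFrame(photo_like_face.image), detector)) == 1

    def test_composite_yields_two_detections(self, detector):
        comp = render_composite(size=160)
        dets = fp.detect_faces(fp.RawFrame(comp), detector)
        assert len(dets) == 2

    def test_color_frame_rejected(self, detector):
        with pytest.raises(fp.FormatError):
            fp.detect_faces(fp.RawFrame(np.zeros((64, 64, 3))), detector)


class TestLocateLandmarks:
    def test_exactly_68_points(self, detector, fixture_face):
        det = fp.detect_faces(fp.RawFrame(fixture_face.image), detector)[0]
        lms = fp.locate_landmarks(fp.RawFrame(fixture_face.image), det)
        assert lms.points.shape == (68, 2)

    def test_translation_equivariance(self, detector):
        a = render_face(size=260, center=(120.0, 130.0))
        b = render_face(size=260, center=(130.0, 140.0))
        da = fp.detect_faces(fp.RawFrame(a.image), detector)[0]
        db = fp.detect_faces(fp.RawFrame(b.image), detector)[0]
        la = fp.locate_landmarks(fp.RawFrame(a.image), da)
        lb = fp.locate_landmarks(fp.RawFrame(b.image), db)
        shift = lb.points - la.points
        np.testing.assert_allclose(shift, np.full_like(shift, 10.0), atol=1.0)

    def test_inner_eye_corners_inside_annotated_boxes(self, detector, fixture_face):
        det = fp.detect_faces(fp.RawFrame(fixture_face.image), detector)[0]
        lms = fp.locate_landmarks(fp.RawFrame(fixture_face.image), det)
        for number, (x0, y0, x1, y1) in fixture_face.eye_boxes.items():
            x, y = lms.point(number)
            assert x0 <= x <= x1 and y0 <= y <= y1

    def test_close_to_ground_truth(self, detector, fixture_face):
        det = fp.detect_faces(fp.RawFrame(fixture_face.image), detector)[0]
        lms = fp.locate_landmarks(fp.RawFrame(fixture_face.image), det)
        err = np.abs(lms.points - fixture_face.landmarks).max()
        assert err < 2.0  # pixels

    def test_flat_crop_raises_landmark_error(self, detector):
        det = fp.FaceDetection((10, 10, 80, 80), 1.0)
        with pytest.raises(fp.LandmarkError):
            fp.locate_landmarks(fp.RawFrame(np.full((100, 100), 200.0)), det)


class TestAlignment:
    def test_horizontal_pair_gives_zero(self):
        assert fp.alignment_angle((10, 20), (30, 20)) == pytest.approx(0.0)

    def test_diagonal_pair_gives_45_degrees(self):
        assert abs(fp.alignment_angle((0, 0), (10, 10))) == pytest.approx(45.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(fp.DegenerateGeometryError):
            fp.alignment_angle((5, 5), (5, 5))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(0.5, 50), st.floats(-89, 89))
    def test_rotation_by_angle_makes_points_corow(self, x, y, dist, theta):
        p40 = np.array([x, y])
        p43 = p40 + dist * np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
        angle = fp.alignment_angle(p40, p43)
        r = np.deg2rad(angle)
        R_inv = np.array([[np.cos(r), np.sin(r)], [-np.sin(r), np.cos(r)]])
        c = (p40 + p43) / 2
        q40, q43 = (R_inv @ (p40 - c) + c), (R_inv @ (p43 - c) + c)
        assert abs(q43[1] - q40[1]) < 0.5

    def test_align_face_levels_rotated_fixture(self, detector):
        face = render_face(size=220, angle_deg=17.0)
        det = fp.detect_faces(fp.RawFrame(face.image), detector)[0]
        lms = fp.locate_landmarks(fp.RawFrame(face.image), det)
        _, aligned_lms, angle = fp.align_face(fp.RawFrame(face.image), lms)
        assert angle == pytest.approx(17.0, abs=2.0)
        assert abs(aligned_lms.point(43)[1] - aligned_lms.point(40)[1]) < 0.5


class TestSections:
    def test_all_sections_are_64x64(self, fixture_face):
        secs = fp.extract_sections(fp.RawFrame(fixture_face.image),
                                   fp.LandmarkSet(fixture_face.landmarks))
        for name in fp.SECTION_NAMES:
            assert getattr(secs, name).shape == (64, 64)

    def test_mirror_symmetric_face_gives_matching_sections(self, fixture_face):
        secs = fp.extract_sections(fp.RawFrame(fixture_face.image),
                                   fp.LandmarkSet(fixture_face.landmarks))
        assert np.abs(secs.eye_left - secs.eye_right_flipped).max() < 1.0
        assert np.abs(secs.mouth_left - secs.mouth_right_flipped).max() < 1.0

    def test_double_flip_restores_section(self, fixture_face):
        secs = fp.extract_sections(fp.RawFrame(fixture_face.image),
                                   fp.LandmarkSet(fixture_face.landmarks))
        np.testing.assert_array_equal(np.fliplr(np.fliplr(secs.eye_left)), secs.eye_left)

    def test_out_of_frame_crop_is_edge_padded(self):
        face = render_face(size=120, center=(10.0, 60.0))  # face mostly off-frame
        secs = fp.extract_sections(fp.RawFrame(face.image), fp.LandmarkSet(face.landmarks))
        for name in fp.SECTION_NAMES:
            arr = getattr(secs, name)
            assert arr.shape == (64, 64)
            assert np.isfinite(arr).all()


class TestEqualizeNormalize:
    def test_constant_section_passes_through(self):
        flat = np.full((64, 64), 77.0)
        np.testing.assert_array_equal(fp.clahe_equalize(flat), flat)

    def test_output_range_stays_in_0_255(self, fixture_face):
        secs = fp.extract_sections(fp.RawFrame(fixture_face.image),
                                   fp.LandmarkSet(fixture_face.landmarks))
        eq = fp.clahe_equalize(secs.eye_left)
        assert eq.min() >= 0 and eq.max() <= 255

    def test_checkerboard_matches_reference_clahe(self):
        from skimage import exposure
        ys, xs = np.mgrid[0:64, 0:64]
        board = np.where((xs // 8 + ys // 8) % 2 == 0, 60.0, 180.0)
        got = fp.clahe_equalize(board, clip=0.02, grid=(8, 8))
        want = exposure.equalize_adapthist(board / 255.0, kernel_size=(8, 8), clip_limit=0.02) * 255.0
        np.testing.assert_allclose(got, want)

    @pytest.mark.parametrize("value,expected", [(255.0, 1.0), (0.0, 0.0), (51.0, 0.2)])
    def test_normalize_linear_map(self, value, expected):
        np.testing.assert_allclose(fp.normalize(np.full((2, 2), value)),
                                   np.full((2, 2), expected))


class TestPreprocess:
    def test_blank_frame_yields_no_face_record(self, detector):
        res = fp.preprocess(fp.RawFrame(np.full((160, 160), 90.0)), detector=detector)
        assert res.face_count == -1
        assert res.sections is None and not res.usable

    def test_fixture_face_yields_valid_sections(self, detector, fixture_face):
        res = fp.preprocess(fp.RawFrame(fixture_face.image), detector=detector)
        assert res.face_count == 1 and res.usable
        for name in fp.SECTION_NAMES:
            arr = getattr(res.sections, name)
            assert arr.shape == (64, 64)
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_deterministic_bit_identical(self, detector, photo_like_face):
        a = fp.preprocess(fp.RawFrame(photo_like_face.image), detector=detector)
        b = fp.preprocess(fp.RawFrame(photo_like_face.image), detector=detector)
        np.testing.assert_array_equal(a.sections.stack(), b.sections.stack())

    def test_save_sections_roundtrip(self, tmp_path, detector, fixture_face):
        import pandas as pd
        results = [
            fp.preprocess(fp.RawFrame(fixture_face.image, frame_index=0, source_path="f0.png"),
                          detector=detector),
            fp.preprocess(fp.RawFrame(np.full((120, 120), 90.0), frame_index=1,
                                      source_path="f1.png"), detector=detector),
        ]
        fp.save_sections(results, tmp_path / "sections.npy", tmp_path / "prov.csv")
        planes = np.load(tmp_path / "sections.npy")
        prov = pd.read_csv(tmp_path / "prov.csv")
        assert planes.shape == (1, 4, 64, 64)
        assert prov.face_count.tolist() == [1, -1]
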