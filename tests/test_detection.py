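import numpy as np
import pytest

from gaitpipe.detection import (BoundingBox, Detection, FrameDetections,
                                Keypoints17, NoPatientInFirstFrame, TrackLost,
                                body_center, crop_square, extract_patient_clip,
                                select_initial_patient, track_patient)
from gaitpipe.synthetic import (MotionSignature, SceneConfig, generate_scene,
                                oracle_backend, oracle_detector)


def _kp_with_hips(lx, ly, rx, ry, conf=0.9):
    pts = np.zeros((17, 3))
    pts[:, 2] = 0.9
    pts[11] = [lx, ly, conf]
    pts[12] = [rx, ry, conf]
    return Keypoints17(points=pts)


def _det(box, kp=None):
    return Detection(box=BoundingBox(*box), keypoints=kp, score=1.0)


class TestBodyCenter:
    def test_hip_midpoint_when_hips_confident(self):
        det = _det((0, 0, 40, 40), _kp_with_hips(10, 20, 30, 20))
        center, flag = body_center(det, tolerance_px=30)
        assert center == (20, 20)
        assert not flag

    def test_box_center_fallback_without_keypoints(self):
        center, flag = body_center(_det((0, 0, 100, 200)))
        assert center == (50, 100)
        assert not flag

    def test_box_center_fallback_on_low_hip_confidence(self):
        det = _det((0, 0, 100, 200), _kp_with_hips(10, 20, 30, 20, conf=0.1))
        center, _ = body_center(det)
        assert center == (50, 100)

    def test_disagreement_flag_keeps_hip_midpoint(self):
        # hips midpoint (20,20), box center (60,20): disagreement 40 > 10
        det = _det((20, 0, 100, 40), _kp_with_hips(10, 20, 30, 20))
        center, flag = body_center(det, tolerance_px=10)
        assert center == (20, 20)
        assert flag


class TestInitialSelection:
    def test_single_detection_returned(self):
        d = _det((0, 0, 10, 10))
        assert select_initial_patient(FrameDetections(0, [d])) is d

    def test_largest_area_wins(self):
        small = _det((0, 0, 10, 10))     # area 100
        large = _det((50, 0, 70, 20))    # area 400
        assert select_initial_patient(FrameDetections(0, [small, large])) is large

    def test_area_tie_breaks_to_lowest_x1(self):
        left = _det((0, 0, 10, 10))
        right = _det((90, 0, 100, 10))
        assert select_initial_patient(FrameDetections(0, [right, left])) is left

    def test_empty_first_frame_raises(self):
        with pytest.raises(NoPatientInFirstFrame):
            select_initial_patient(FrameDetections(0, []))


class TestTracking:
    def test_single_person_track_equals_detections(self, simple_scene):
        frames = oracle_backend(simple_scene)
        track = track_patient(frames)
        assert len(track) == len(frames)
        for e, fd in zip(track.entries, frames):
            assert e.detection.box == fd.detections[0].box
        assert track.gap_frames == []

    def test_identity_held_through_distractor_entry(self, distractor_scene):
        """Nearest-center association never jumps to the trailing figure."""
        frames = oracle_backend(distractor_scene)
        track = track_patient(frames)
        for e in track.entries:
            truth = distractor_scene.truth[e.frame_index]
            tag = next(t for t, box, _ in truth if box == e.detection.box)
            assert tag == "patient"

    def test_tie_goes_to_first_detection(self):
        a = _det((0, 0, 10, 10))
        frames = [
            FrameDetections(0, [_det((4, 0, 6, 10))]),  # center (5, 5)
            FrameDetections(1, [_det((0, 0, 10, 10)), _det((0, 0, 10, 10))]),
        ]
        track = track_patient(frames)
        assert track.entries[1].detection is frames[1].detections[0]

    def test_gap_carryover_and_track_lost(self):
        d = _det((0, 0, 10, 10))
        frames = [FrameDetections(0, [d])] + \
            [FrameDetections(i, []) for i in range(1, 4)]
        track = track_patient(frames, max_gap=5)
        assert track.gap_frames == [1, 2, 3]
        assert all(e.carried_over for e in track.entries[1:])
        frames = [FrameDetections(0, [d])] + \
            [FrameDetections(i, []) for i in range(1, 8)]
        with pytest.raises(TrackLost):
            track_patient(frames, max_gap=5)


class TestCropSquare:
    def test_source_square_from_box_height(self):
        # side = y2 - y1 = 200, half-side 100 around center (140, 300)
        frame = np.zeros((480, 640, 3), np.uint8)
        frame[200:400, 40:240] = 255  # exactly the expected source square
        out = crop_square(frame, BoundingBox(100, 200, 180, 400), (140, 300),
                          out_side=100)
        assert out.shape == (100, 100, 3)
        assert out.min() == 255  # nothing outside the square leaked in

    def test_edge_replication_fills_left_shortfall(self):
        # center x=20, s=200 -> 80 replicated columns on the left
        frame = np.zeros((400, 640, 3), np.uint8)
        frame[:, 0] = [7, 7, 7]
        out = crop_square(frame, BoundingBox(0, 100, 40, 300), (20, 200),
                          out_side=200)
        assert np.all(out[:, :80] == 7)

    def test_zero_fill_mode(self):
        frame = np.full((400, 640, 3), 9, np.uint8)
        out = crop_square(frame, BoundingBox(0, 100, 40, 300), (20, 200),
                          out_side=200, fill="zero")
        assert np.all(out[:, :80] == 0)

    def test_output_shape_is_always_square_rgb(self, simple_scene):
        _, box, _ = simple_scene.truth[0][0]
        out = crop_square(simple_scene.frames[0], box, box.center)
        assert out.shape == (512, 512, 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(0, 10, 10, 10)


class TestExtractPatientClip:
    def test_one_output_per_input_frame(self, simple_scene):
        crops, track = extract_patient_clip(
            simple_scene.frames, oracle_backend(simple_scene), out_side=64)
        assert crops.shape == (len(simple_scene.frames), 64, 64, 3)
        assert len(track) == len(simple_scene.frames)

    def test_crop_centers_match_ground_truth(self, simple_scene):
        """Tracked center equals the true hip midpoint within a pixel."""
        _, track = extract_patient_clip(
            simple_scene.frames, oracle_backend(simple_scene), out_side=64)
        for e in track.entries:
            _, _, kp = simple_scene.truth[e.frame_index][0]
            hx, hy = kp.hip_midpoint()
            assert abs(e.center[0] - hx) <= 1 and abs(e.center[1] - hy) <= 1

    def test_errors_propagate(self, simple_scene):
        empty = [FrameDetections(i, []) for i in range(len(simple_scene.frames))]
        with pytest.raises(NoPatientInFirstFrame):
            extract_patient_clip(simple_scene.frames, empty)


class TestIdentitySafety:
    @pytest.mark.parametrize("seed", range(20))
    def test_no_identity_switch_over_seeds(self, seed):
        """With inter-person gap >= 2x the per-frame displacement the
        nearest-neighbor rule provably never switches identity."""
        sig = MotionSignature(stride_px=4.0)
        cfg = SceneConfig(n_frames=35, seed=seed, patient_signature=sig,
                          distractor_entry_frame=2, distractor_gap_px=50.0)
        scene = generate_scene(cfg)
        assert any(len(t) == 2 for t in scene.truth)  # distractor did appear
        track = track_patient(oracle_backend(scene))
        for e in track.entries:
            truth = scene.truth[e.frame_index]
            tag = next(t for t, box, _ in truth if box == e.detection.box)
            assert tag == "patient"
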