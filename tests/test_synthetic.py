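import numpy as np
import pytest

from gaitpipe.synthetic import (ASD_MEAN, NON_ASD_MEAN, MotionSignature,
                                SceneConfig, generate_cohort, generate_scene,
                                oracle_detector, truth_to_json)


class TestSceneGeneration:
    def test_determinism_bitwise(self):
        cfg = SceneConfig(n_frames=20, seed=5, distractor_entry_frame=8,
                          distractor_gap_px=60.0)
        a, b = generate_scene(cfg), generate_scene(cfg)
        assert np.array_equal(a.frames, b.frames)
        for ta, tb in zip(a.truth, b.truth):
            for (tag_a, box_a, kp_a), (tag_b, box_b, kp_b) in zip(ta, tb):
                assert tag_a == tag_b and box_a == box_b
                assert np.array_equal(kp_a.points, kp_b.points)

    def test_person_counts_around_distractor_entry(self):
        cfg = SceneConfig(n_frames=30, seed=2, distractor_entry_frame=10,
                          distractor_gap_px=40.0)
        scene = generate_scene(cfg)
        for i, people in enumerate(scene.truth):
            assert len(people) == (1 if i < 10 else 2)

    def test_frame_zero_has_exactly_one_person(self):
        for seed in range(5):
            scene = generate_scene(SceneConfig(n_frames=5, seed=seed,
                                               distractor_entry_frame=1,
                                               distractor_gap_px=30.0))
            assert len(scene.truth[0]) == 1

    def test_box_center_advances_by_stride(self):
        sig = MotionSignature(stride_px=4.0)
        scene = generate_scene(SceneConfig(n_frames=30, seed=3,
                                           patient_signature=sig))
        cx = [people[0][1].center[0] for people in scene.truth]
        assert np.all(np.abs(np.diff(cx) - 4.0) <= 1.0)

    def test_box_matches_rendered_figure(self):
        """The truth box contains the rendered figure's pixels."""
        scene = generate_scene(SceneConfig(n_frames=10, seed=4))
        for i in (0, 5, 9):
            _, box, _ = scene.truth[i][0]
            figure = np.all(scene.frames[i] == (40, 40, 90), axis=2)
            ys, xs = np.nonzero(figure)
            inside = ((xs >= box.x1) & (xs < box.x2)
                      & (ys >= box.y1) & (ys < box.y2))
            assert inside.mean() > 0.99

    def test_truncation_instead_of_wraparound(self):
        sig = MotionSignature(stride_px=30.0)
        scene = generate_scene(SceneConfig(n_frames=100, seed=1,
                                           patient_signature=sig))
        assert scene.truncated
        assert len(scene.frames) < 100
        for people in scene.truth:
            for _, box, _ in people:
                assert box.x1 >= 0 and box.x2 <= scene.config.frame_width

    def test_truth_boxes_within_frame_bounds(self, distractor_scene):
        w = distractor_scene.config.frame_width
        h = distractor_scene.config.frame_height
        for people in distractor_scene.truth:
            for _, box, _ in people:
                assert 0 <= box.x1 < box.x2 <= w
                assert 0 <= box.y1 < box.y2 <= h

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(n_frames=0)
        with pytest.raises(ValueError):
            SceneConfig(distractor_entry_frame=0)
        with pytest.raises(ValueError):
            MotionSignature(stride_px=0)


class TestOracleDetector:
    def test_single_person_before_entry(self, distractor_scene):
        fd = oracle_detector(distractor_scene, 5)
        assert len(fd.detections) == 1
        assert fd.detections[0].score == 1.0

    def test_boxes_equal_truth_exactly(self, distractor_scene):
        for i in range(len(distractor_scene.frames)):
            fd = oracle_detector(distractor_scene, i)
            for det, (_, box, _) in zip(fd.detections,
                                        distractor_scene.truth[i]):
                assert det.box == box

    def test_hip_midpoint_inside_box(self, distractor_scene):
        for i in range(len(distractor_scene.frames)):
            for det in oracle_detector(distractor_scene, i).detections:
                hx, hy = det.keypoints.hip_midpoint()
                assert det.box.contains(hx, hy)

    def test_out_of_range_index(self, simple_scene):
        with pytest.raises(IndexError):
            oracle_detector(simple_scene, len(simple_scene.frames))


class TestCohort:
    def test_class_ratio_realised(self):
        cohort = generate_cohort(12, 0.5, clips_per_patient=1, seed=0)
        labels = list(cohort.labels().values())
        assert labels.count("ASD") == 6 and labels.count("non-ASD") == 6

    def test_determinism(self):
        a = generate_cohort(6, 0.5, clips_per_patient=1, seed=9)
        b = generate_cohort(6, 0.5, clips_per_patient=1, seed=9)
        assert a.labels() == b.labels()
        for (_, _, sa), (_, _, sb) in zip(a.patients, b.patients):
            assert np.array_equal(sa[0].frames, sb[0].frames)

    def test_patient_ids_unique_and_scene_length(self):
        cohort = generate_cohort(8, 0.5, clips_per_patient=2, seed=1)
        pids = [p for p, _, _ in cohort.patients]
        assert len(pids) == len(set(pids))
        for _, _, scenes in cohort.patients:
            assert len(scenes[0].frames) == 60  # 2 clips x 30 frames
            assert not scenes[0].truncated

    def test_zero_separation_collapses_class_means(self):
        a = generate_cohort(10, 0.5, 1, seed=2, separation=0.0)
        sigs = {lab: [] for lab in ("ASD", "non-ASD")}
        for _, lab, scenes in a.patients:
            sigs[lab].append(scenes[0].config.patient_signature.trunk_pitch_deg)
        # jitter sigma is 2 degrees; collapsed means differ far less than
        # the default separation (24 degrees)
        assert abs(np.mean(sigs["ASD"]) - np.mean(sigs["non-ASD"])) < 5.0

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, 0.5)
        with pytest.raises(ValueError):
            generate_cohort(10, 0.0)

    def test_signature_separation_defaults(self):
        assert ASD_MEAN.trunk_pitch_deg > NON_ASD_MEAN.trunk_pitch_deg + 15


class TestSidecar:
    def test_truth_json_round_trip_fields(self, simple_scene):
        import json
        payload = json.loads(truth_to_json(simple_scene))
        assert payload["truncated"] is False
        assert len(payload["frames"]) == len(simple_scene.frames)
        first = payload["frames"][0][0]
        assert first["tag"] == "patient"
        assert len(first["keypoints"]) == 17
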