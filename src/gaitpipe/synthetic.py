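"""Synthetic side-view walking scenes with exact ground truth.

Emulates the structure of a clinical gait recording: a single walking
figure crosses a fixed side-view camera in front of a static, cluttered
background; optionally a second figure (the accompanying doctor) enters
some frames later and trails the first at a guaranteed distance.  Class
identity is carried by a kinematic signature — chiefly forward trunk
pitch and head drop, the visually dominant features of sagittal-plane
spinal deformity — so that a downstream classifier has a real, tunable
signal to recover.

Figures are articulated stick figures (elliptical head, thick limb
segments) rasterised with scikit-image draw primitives.  Every frame
carries exact ground truth: per-person bounding box and 17 keypoints in
COCO ordering (only the hips are kinematically meaningful; the rest are
placed schematically on the skeleton).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk, line

from .detection import BoundingBox, Detection, FrameDetections, Keypoints17

COCO_KEYPOINT_NAMES = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)
LEFT_HIP, RIGHT_HIP = 11, 12


@dataclass(frozen=True)
class MotionSignature:
    """Kinematic parameters of one walking figure.

    trunk_pitch_deg : forward lean of the torso from vertical (degrees).
    head_drop_deg   : additional forward/downward pitch of the head
                      relative to the torso axis (degrees).
    stride_px       : horizontal advance per frame (pixels).
    sway_px         : vertical bob amplitude over the gait cycle (pixels).
    limb_phase      : phase offset of the limb oscillation, in [0, 2*pi).
    """

    trunk_pitch_deg: float = 5.0
    head_drop_deg: float = 5.0
    stride_px: float = 4.0
    sway_px: float = 2.0
    limb_phase: float = 0.0

    def __post_init__(self):
        if self.trunk_pitch_deg < 0 or self.head_drop_deg < 0 or self.sway_px < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.stride_px <= 0:
            raise ValueError("stride_px must be > 0")


@dataclass(frozen=True)
class SceneConfig:
    frame_width: int = 640
    frame_height: int = 360
    fps: int = 30
    n_frames: int = 60
    patient_signature: MotionSignature = field(default_factory=MotionSignature)
    distractor_entry_frame: int | None = None
    distractor_gap_px: float = 120.0
    background_clutter: int = 6
    figure_height_px: float | None = None  # default: 60% of frame height
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fps < 1:
            raise ValueError("fps must be >= 1")
        if self.distractor_entry_frame is not None and self.distractor_entry_frame < 1:
            raise ValueError("distractor must enter at frame >= 1 "
                             "(the patient is always alone in frame 0)")


@dataclass
class SyntheticScene:
    frames: np.ndarray            # (n, H, W, 3) uint8
    truth: list[list[tuple]]      # per frame: [(tag, BoundingBox, Keypoints17), ...]
    config: SceneConfig
    truncated: bool = False       # figure left the frame before n_frames

    def __len__(self):
        return len(self.frames)


@dataclass
class CohortDataset:
    """Patients with class labels and their synthetic walking scenes."""

    patients: list[tuple[str, str, list[SyntheticScene]]]
    class_ratio: float

    def labels(self) -> dict[str, str]:
        return {pid: label for pid, label, _ in self.patients}


# ---------------------------------------------------------------------------
# figure geometry

def _skeleton(x: float, ground_y: float, sig: MotionSignature, phase: float,
              height: float):
    """Joint positions (x, y) for one figure; y grows downward.

    ``x`` is the hip x-position, ``ground_y`` the foot line, ``phase`` the
    gait-cycle phase in radians.
    """
    leg = 0.48 * height
    torso = 0.34 * height
    head_r = 0.09 * height
    bob = sig.sway_px * 0.5 * (1 + np.sin(2 * phase))
    hip_y = ground_y - leg + bob
    hip = np.array([x, hip_y])
    pitch = np.deg2rad(sig.trunk_pitch_deg)
    neck = hip + torso * np.array([np.sin(pitch), -np.cos(pitch)])
    head_pitch = pitch + np.deg2rad(sig.head_drop_deg)
    head = neck + 1.6 * head_r * np.array([np.sin(head_pitch), -np.cos(head_pitch)])
    # legs: sinusoidal swing around vertical
    swing = 0.35 * np.sin(phase)
    knee_l = hip + 0.5 * leg * np.array([np.sin(swing), np.cos(swing)])
    ankle_l = hip + leg * np.array([np.sin(swing), np.cos(swing)])
    knee_r = hip + 0.5 * leg * np.array([np.sin(-swing), np.cos(-swing)])
    ankle_r = hip + leg * np.array([np.sin(-swing), np.cos(-swing)])
    # arms: counter-phase swing from the neck
    arm = 0.36 * height
    a_swing = 0.4 * np.sin(phase + np.pi)
    elbow_l = neck + 0.5 * arm * np.array([np.sin(pitch + a_swing), np.cos(pitch + a_swing)])
    wrist_l = neck + arm * np.array([np.sin(pitch + a_swing), np.cos(pitch + a_swing)])
    elbow_r = neck + 0.5 * arm * np.array([np.sin(pitch - a_swing), np.cos(pitch - a_swing)])
    wrist_r = neck + arm * np.array([np.sin(pitch - a_swing), np.cos(pitch - a_swing)])
    return {
        "hip": hip, "neck": neck, "head": head, "head_r": head_r,
        "knee_l": knee_l, "ankle_l": ankle_l, "knee_r": knee_r, "ankle_r": ankle_r,
        "elbow_l": elbow_l, "wrist_l": wrist_l, "elbow_r": elbow_r, "wrist_r": wrist_r,
    }


def _keypoints(sk: dict) -> Keypoints17:
    """Schematic COCO-17 keypoints from the skeleton; hips flank the pelvis."""
    head, neck, hip = sk["head"], sk["neck"], sk["hip"]
    r = sk["head_r"]
    pts = np.zeros((17, 3), dtype=np.float64)
    pts[:, 2] = 1.0
    pts[0, :2] = head + [0.6 * r, 0]                     # nose (profile view)
    pts[1, :2] = head + [0.3 * r, -0.3 * r]              # eyes
    pts[2, :2] = head + [0.2 * r, -0.3 * r]
    pts[3, :2] = head + [-0.3 * r, 0]                    # ears
    pts[4, :2] = head + [-0.4 * r, 0]
    pts[5, :2] = neck + [2.0, 2.0]                       # shoulders
    pts[6, :2] = neck + [-2.0, 2.0]
    pts[7, :2] = sk["elbow_l"]
    pts[8, :2] = sk["elbow_r"]
    pts[9, :2] = sk["wrist_l"]
    pts[10, :2] = sk["wrist_r"]
    pts[11, :2] = hip + [3.0, 0.0]                       # left hip
    pts[12, :2] = hip + [-3.0, 0.0]                      # right hip
    pts[13, :2] = sk["knee_l"]
    pts[14, :2] = sk["knee_r"]
    pts[15, :2] = sk["ankle_l"]
    pts[16, :2] = sk["ankle_r"]
    return Keypoints17(points=pts)


def _figure_extents(sig: MotionSignature, ground_y: float, height: float,
                    n_phases: int = 64) -> tuple[float, float, float, float]:
    """Phase-independent extents (x1, y1, x2, y2) of a figure whose hip sits
    at x = 0, taken over a full gait cycle.

    Using cycle-wide extents makes the ground-truth box rigid: it translates
    exactly with the hip, so its center advances stride_px per frame.
    """
    xs, ys = [], []
    for phase in np.linspace(0, 2 * np.pi, n_phases, endpoint=False):
        sk = _skeleton(0.0, ground_y, sig, phase, height)
        kp = _keypoints(sk)
        xs.extend(kp.points[:, 0])
        ys.extend(kp.points[:, 1])
        xs.extend([sk["head"][0] - sk["head_r"], sk["head"][0] + sk["head_r"]])
        ys.extend([sk["head"][1] - sk["head_r"], sk["head"][1] + sk["head_r"]])
    m = 3.0  # limb half-thickness margin
    return (min(xs) - m, min(ys) - m, max(xs) + m, max(ys) + m)


def _draw_thick_line(img, p0, p1, color, rad=2):
    h, w = img.shape[:2]
    rr, cc = line(int(round(p0[1])), int(round(p0[0])),
                  int(round(p1[1])), int(round(p1[0])))
    for dr in range(-rad, rad + 1):
        for dc in range(-rad, rad + 1):
            r, c = rr + dr, cc + dc
            ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
            img[r[ok], c[ok]] = color


def _draw_figure(img, sk, color):
    _draw_thick_line(img, sk["hip"], sk["neck"], color, rad=3)
    for a, b in (("hip", "knee_l"), ("knee_l", "ankle_l"),
                 ("hip", "knee_r"), ("knee_r", "ankle_r"),
                 ("neck", "elbow_l"), ("elbow_l", "wrist_l"),
                 ("neck", "elbow_r"), ("elbow_r", "wrist_r")):
        _draw_thick_line(img, sk[a], sk[b], color, rad=2)
    rr, cc = disk((sk["head"][1], sk["head"][0]), sk["head_r"],
                  shape=img.shape[:2])
    img[rr, cc] = color


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.frame_height, cfg.frame_width
    img = np.full((h, w, 3), 200, dtype=np.uint8)
    # mild deterministic texture
    tex = (rng.integers(-12, 12, size=(h, w, 1))).astype(np.int16)
    img = np.clip(img.astype(np.int16) + tex, 0, 255).astype(np.uint8)
    for _ in range(cfg.background_clutter):
        x0 = int(rng.integers(0, max(1, w - 40)))
        y0 = int(rng.integers(0, max(1, h - 40)))
        bw = int(rng.integers(20, 120))
        bh = int(rng.integers(20, 120))
        color = rng.integers(60, 180, size=3)
        img[y0:min(h, y0 + bh), x0:min(w, x0 + bw)] = color
    return img


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a deterministic walking scene with per-frame ground truth.

    The patient enters at the left and advances ``stride_px`` per frame;
    if ``distractor_entry_frame`` is set a second figure appears from that
    frame on, trailing the patient by at least ``distractor_gap_px``.  If
    a figure would leave the frame before ``n_frames`` the scene is
    truncated and flagged, never wrapped around.
    """
    rng = np.random.default_rng(config.seed)
    bg = _background(config, rng)
    h, w = config.frame_height, config.frame_width
    height = config.figure_height_px or 0.6 * h
    ground_y = 0.92 * h
    sig = config.patient_signature
    x0 = 0.12 * w
    patient_color = np.array([40, 40, 90], dtype=np.uint8)
    doctor_color = np.array([90, 40, 40], dtype=np.uint8)
    d_sig = replace(sig, trunk_pitch_deg=2.0, head_drop_deg=0.0,
                    limb_phase=sig.limb_phase + 1.3)
    ext = _figure_extents(sig, ground_y, height)
    d_ext = _figure_extents(d_sig, ground_y, height)

    frames, truth = [], []
    truncated = False
    for f in range(config.n_frames):
        px = x0 + sig.stride_px * f
        phase = sig.limb_phase + 2 * np.pi * f * 1.6 / config.fps
        sk = _skeleton(px, ground_y, sig, phase, height)
        kp = _keypoints(sk)
        box = BoundingBox(px + ext[0], ext[1], px + ext[2], ext[3])
        if box.x2 > w or box.x1 < 0:
            truncated = True
            break
        img = bg.copy()
        people = []
        _draw_figure(img, sk, patient_color)
        people.append(("patient", box, kp))
        if (config.distractor_entry_frame is not None
                and f >= config.distractor_entry_frame):
            # exact trail: the gap guarantee holds by construction
            dx = px - config.distractor_gap_px
            d_phase = d_sig.limb_phase + 2 * np.pi * f * 1.6 / config.fps
            d_sk = _skeleton(dx, ground_y, d_sig, d_phase, height)
            d_kp = _keypoints(d_sk)
            d_box = BoundingBox(dx + d_ext[0], d_ext[1], dx + d_ext[2], d_ext[3])
            if d_box.x1 >= 0 and d_box.x2 <= w:
                _draw_figure(img, d_sk, doctor_color)
                people.append(("distractor", d_box, d_kp))
        frames.append(img)
        truth.append(people)
    if not frames:
        raise ValueError("figure does not fit in the frame at all")
    return SyntheticScene(frames=np.stack(frames), truth=truth,
                          config=config, truncated=truncated)


def oracle_detector(scene: SyntheticScene, frame_index: int) -> FrameDetections:
    """Ground truth re-emitted as detections (confidence 1.0, tags stripped).

    Serves as the exact detector backend for testing the tracking and
    cropping contracts without any learned person detector.
    """
    if not 0 <= frame_index < len(scene.frames):
        raise IndexError(f"frame_index {frame_index} out of range")
    dets = [Detection(box=box, keypoints=kp, score=1.0)
            for _, box, kp in scene.truth[frame_index]]
    return FrameDetections(frame_index=frame_index, detections=dets)


def oracle_backend(scene: SyntheticScene):
    """Detector-backend callable over a whole scene."""
    return [oracle_detector(scene, i) for i in range(len(scene.frames))]


# ---------------------------------------------------------------------------
# cohorts

#: class-mean signatures: ASD walks with pronounced forward trunk pitch and
#: head drop; the non-ASD pool walks close to upright.
ASD_MEAN = MotionSignature(trunk_pitch_deg=28.0, head_drop_deg=22.0,
                           stride_px=3.5, sway_px=3.0)
NON_ASD_MEAN = MotionSignature(trunk_pitch_deg=4.0, head_drop_deg=2.0,
                               stride_px=4.0, sway_px=2.0)


def _jittered(mean: MotionSignature, rng: np.random.Generator) -> MotionSignature:
    return MotionSignature(
        trunk_pitch_deg=max(0.0, mean.trunk_pitch_deg + rng.normal(0, 2.0)),
        head_drop_deg=max(0.0, mean.head_drop_deg + rng.normal(0, 2.0)),
        stride_px=max(1.0, mean.stride_px + rng.normal(0, 0.3)),
        sway_px=max(0.0, mean.sway_px + rng.normal(0, 0.5)),
        limb_phase=float(rng.uniform(0, 2 * np.pi)),
    )


def _blend(a: MotionSignature, b: MotionSignature, w: float) -> MotionSignature:
    """Signature at fraction ``w`` along the line from the pooled mean to ``a``."""
    mid = {f: 0.5 * (getattr(a, f) + getattr(b, f))
           for f in ("trunk_pitch_deg", "head_drop_deg", "stride_px", "sway_px")}
    return MotionSignature(**{f: mid[f] + w * (getattr(a, f) - mid[f]) for f in mid})


def generate_cohort(n_patients: int, class_ratio: float = 0.5,
                    clips_per_patient: int = 4, seed: int = 0, *,
                    separation: float = 1.0,
                    frame_width: int = 640, frame_height: int = 360,
                    fps: int = 30,
                    distractor_entry_frame: int | None = None) -> CohortDataset:
    """Generate a labelled patient cohort of synthetic walking scenes.

    ``class_ratio`` is the ASD fraction; labels are assigned to match it
    (rounded), with at least one patient per class.  ``separation`` scales
    the distance between the two class-mean signatures: 1 keeps the
    defaults, 0 collapses both classes onto the pooled mean (no signal).
    Each scene holds ``clips_per_patient`` seconds of video.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients to realise both classes")
    if not 0 < class_ratio < 1:
        raise ValueError("class_ratio must be strictly between 0 and 1")
    n_asd = int(round(n_patients * class_ratio))
    n_asd = min(max(n_asd, 1), n_patients - 1)
    rng = np.random.default_rng(seed)
    labels = np.array(["ASD"] * n_asd + ["non-ASD"] * (n_patients - n_asd))
    rng.shuffle(labels)
    asd_mean = _blend(ASD_MEAN, NON_ASD_MEAN, separation)
    non_mean = _blend(NON_ASD_MEAN, ASD_MEAN, separation)
    patients = []
    for i, label in enumerate(labels):
        mean = asd_mean if label == "ASD" else non_mean
        sig = _jittered(mean, rng)
        n_frames = clips_per_patient * fps
        # keep the walk inside the frame: shrink stride if necessary
        max_stride = (0.85 * frame_width - 0.12 * frame_width) / max(n_frames, 1)
        if sig.stride_px > max_stride:
            sig = replace(sig, stride_px=max(1.0, max_stride))
        cfg = SceneConfig(frame_width=frame_width, frame_height=frame_height,
                          fps=fps, n_frames=n_frames, patient_signature=sig,
                          distractor_entry_frame=distractor_entry_frame,
                          seed=int(rng.integers(0, 2**31 - 1)))
        scene = generate_scene(cfg)
        patients.append((f"P{i:03d}", str(label), [scene]))
    return CohortDataset(patients=patients, class_ratio=class_ratio)


# ---------------------------------------------------------------------------
# sidecar I/O

def truth_to_json(scene: SyntheticScene) -> str:
    """Ground truth as a JSON sidecar string (boxes + keypoint triples)."""
    payload = []
    for frame_people in scene.truth:
        payload.append([
            {
                "tag": tag,
                "box": [box.x1, box.y1, box.x2, box.y2],
                "keypoints": kp.points.tolist(),
            }
            for tag, box, kp in frame_people
        ])
    return json.dumps({"truncated": scene.truncated, "frames": payload})
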