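"""Detection stage: locate the patient per frame, keep their identity when
a second person enters, and emit square patient-centered crops.

The stage is backend-agnostic: any per-frame person detector satisfying
the :class:`Detection` contract (bounding box, optional COCO-17 keypoints,
confidence) can drive it.  The tests and the synthetic pipeline use the
exact ground-truth oracle from :mod:`gaitpipe.synthetic`; a learned
region-based detector with a keypoint head can be plugged in identically.

Tracking follows a first-entrant prior: the patient is the person present
in frame 0 (the accompanying doctor, if any, enters later), and between
adjacent frames the same person moves the shortest distance, so the track
always continues with the detection whose body center is nearest to the
previous one.

Coordinates are 0-based with half-open boxes [x1, x2) x [y1, y2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEFT_HIP, RIGHT_HIP = 11, 12
#: keypoint visibility cutoff below which the box center is used instead
HIP_CONFIDENCE_THRESHOLD = 0.3


@dataclass(frozen=True)
class BoundingBox:
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(f"degenerate box {self}")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def contains(self, x: float, y: float) -> bool:
        return self.x1 <= x < self.x2 and self.y1 <= y < self.y2


@dataclass(frozen=True)
class Keypoints17:
    """17 (x, y, confidence) triples in COCO ordering (11/12 = hips)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (17, 3):
            raise ValueError(f"expected (17, 3) keypoints, got {pts.shape}")
        if np.any(pts[:, 2] < 0) or np.any(pts[:, 2] > 1):
            raise ValueError("keypoint confidences must lie in [0, 1]")
        object.__setattr__(self, "points", pts)

    def hip_midpoint(self) -> tuple[float, float] | None:
        """Midpoint of the two hip keypoints, or None if either is below
        the visibility cutoff."""
        lh, rh = self.points[LEFT_HIP], self.points[RIGHT_HIP]
        if lh[2] < HIP_CONFIDENCE_THRESHOLD or rh[2] < HIP_CONFIDENCE_THRESHOLD:
            return None
        return (0.5 * (lh[0] + rh[0]), 0.5 * (lh[1] + rh[1]))


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    keypoints: Keypoints17 | None = None
    score: float = 1.0

    def __post_init__(self):
        if not 0 <= self.score <= 1:
            raise ValueError("score must lie in [0, 1]")


@dataclass(frozen=True)
class FrameDetections:
    frame_index: int
    detections: list[Detection]

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass
class TrackEntry:
    frame_index: int
    detection: Detection
    center: tuple[float, float]
    carried_over: bool = False


@dataclass
class PatientTrack:
    entries: list[TrackEntry]
    gap_frames: list[int] = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def centers(self) -> np.ndarray:
        return np.array([e.center for e in self.entries])


class NoPatientInFirstFrame(RuntimeError):
    """Frame 0 held no detection: the first-entrant prior is violated."""


class TrackLost(RuntimeError):
    """More than max_gap consecutive frames without any detection."""


def body_center(det: Detection, tolerance_px: float = 10.0
                ) -> tuple[tuple[float, float], bool]:
    """Body center of a detection, plus a disagreement flag.

    The center is the midpoint of the two hip keypoints when both are
    confidently visible, else the bounding-box center.  When both sources
    are available the flag reports whether they disagree by more than
    ``tolerance_px`` (Euclidean); the hip midpoint is returned either way.
    """
    box_center = det.box.center
    hip = det.keypoints.hip_midpoint() if det.keypoints is not None else None
    if hip is None:
        return box_center, False
    dist = float(np.hypot(hip[0] - box_center[0], hip[1] - box_center[1]))
    return hip, dist > tolerance_px


def select_initial_patient(first: FrameDetections) -> Detection:
    """The patient in frame 0: the sole detection, or the largest box
    (ties broken toward the lowest x1)."""
    if first.frame_index != 0:
        raise ValueError("initial selection requires frame 0")
    if not first.detections:
        raise NoPatientInFirstFrame("no person detected in frame 0")
    return max(first.detections, key=lambda d: (d.box.area, -d.box.x1))


def track_patient(frames: list[FrameDetections], max_gap: int = 5,
                  tolerance_px: float = 10.0) -> PatientTrack:
    """Follow the patient across frames by nearest-center association.

    Initialised from frame 0 via :func:`select_initial_patient`; each
    subsequent frame continues with the detection whose body center is
    nearest (Euclidean) to the previous chosen center, ties going to the
    lowest detection index.  Frames with no detection carry the previous
    detection over (recorded in ``gap_frames``); more than ``max_gap``
    consecutive empty frames raise :class:`TrackLost`.
    """
    if not frames or frames[0].frame_index != 0:
        raise ValueError("tracking requires detections starting at frame 0")
    chosen = select_initial_patient(frames[0])
    center, _ = body_center(chosen, tolerance_px)
    entries = [TrackEntry(0, chosen, center)]
    gaps: list[int] = []
    consecutive_empty = 0
    for fd in frames[1:]:
        if fd.frame_index != entries[-1].frame_index + 1:
            raise ValueError("frame indices must be contiguous")
        if not fd.detections:
            consecutive_empty += 1
            if consecutive_empty > max_gap:
                raise TrackLost(
                    f"no detection for {consecutive_empty} consecutive frames "
                    f"(max_gap={max_gap}) at frame {fd.frame_index}")
            gaps.append(fd.frame_index)
            entries.append(TrackEntry(fd.frame_index, chosen, center,
                                      carried_over=True))
            continue
        consecutive_empty = 0
        centers = [body_center(d, tolerance_px)[0] for d in fd.detections]
        dists = [np.hypot(c[0] - center[0], c[1] - center[1]) for c in centers]
        idx = int(np.argmin(dists))  # argmin takes the first minimum: tie rule
        chosen, center = fd.detections[idx], centers[idx]
        entries.append(TrackEntry(fd.frame_index, chosen, center))
    return PatientTrack(entries=entries, gap_frames=gaps)


def crop_square(frame: np.ndarray, box: BoundingBox,
                center: tuple[float, float], out_side: int = 512,
                fill: str = "edge") -> np.ndarray:
    """Square patient crop: side = box height, centered on the body center,
    out-of-frame regions filled, then resized isotropically to
    ``out_side`` x ``out_side``.

    The source square keeps the person's aspect ratio by construction
    (height drives the side; the sides are filled rather than stretched).
    ``fill`` is ``"edge"`` (edge-pixel replication, default) or ``"zero"``.
    """
    s = box.height
    if s <= 0:
        raise ValueError("box height must be positive")
    if out_side < 1:
        raise ValueError("out_side must be >= 1")
    side = int(round(s))
    half = side / 2.0
    x0 = int(round(center[0] - half))
    y0 = int(round(center[1] - half))
    x1, y1 = x0 + side, y0 + side
    h, w = frame.shape[:2]
    pad_l, pad_t = max(0, -x0), max(0, -y0)
    pad_r, pad_b = max(0, x1 - w), max(0, y1 - h)
    sub = frame[max(0, y0):min(h, y1), max(0, x0):min(w, x1)]
    if any((pad_l, pad_t, pad_r, pad_b)):
        mode = "edge" if fill == "edge" else "constant"
        sub = np.pad(sub, ((pad_t, pad_b), (pad_l, pad_r), (0, 0)), mode=mode)
    return _resize_isotropic(sub, out_side)


def _resize_isotropic(img: np.ndarray, out_side: int) -> np.ndarray:
    """Bilinear square-to-square resize (equal scale factors by construction)."""
    from skimage.transform import resize
    if img.shape[0] != img.shape[1]:
        raise ValueError("crop source must be square")
    if img.shape[0] == out_side:
        return img.copy()
    out = resize(img.astype(np.float64), (out_side, out_side),
                 order=1, anti_aliasing=img.shape[0] > out_side,
                 preserve_range=True)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def extract_patient_clip(frames: np.ndarray,
                         detections: list[FrameDetections],
                         out_side: int = 512, max_gap: int = 5,
                         tolerance_px: float = 10.0,
                         fill: str = "edge") -> tuple[np.ndarray, PatientTrack]:
    """Run the full detection stage over a video.

    Returns one ``out_side`` x ``out_side`` crop per input frame, each
    centered on the tracked patient, together with the track for audit.
    """
    if len(frames) == 0:
        raise ValueError("empty video")
    if len(detections) != len(frames):
        raise ValueError("need one FrameDetections per frame")
    track = track_patient(detections, max_gap=max_gap, tolerance_px=tolerance_px)
    crops = np.stack([
        crop_square(frames[e.frame_index], e.detection.box, e.center,
                    out_side=out_side, fill=fill)
        for e in track.entries
    ])
    return crops, track


def track_to_json(track: PatientTrack) -> dict:
    """Track audit record (per-frame box, center, carry-over flag)."""
    return {
        "gap_frames": list(track.gap_frames),
        "entries": [
            {
                "frame": e.frame_index,
                "box": [e.detection.box.x1, e.detection.box.y1,
                        e.detection.box.x2, e.detection.box.y2],
                "center": list(e.center),
                "carried_over": e.carried_over,
            }
            for e in track.entries
        ],
    }
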