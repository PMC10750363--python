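"""Clip pipeline: slice cropped video into 1-second shots, sample T=8
frames uniformly, and prepare model-ready tensors.

A 30 FPS video yields non-overlapping 30-frame clips (trailing remainder
dropped); from each clip T frames are taken at indices floor(k*F/T),
k = 0..T-1 — the stride-based uniform sampling used throughout clip-based
action recognition.  For F=30, T=8 this gives [0, 3, 7, 11, 15, 18, 22, 26].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import _resize_isotropic

#: disease-code -> binary label mapping
DISEASE_TO_LABEL = {"ASD": "ASD", "DHS": "non-ASD", "LCS": "non-ASD",
                    "HipOA": "non-ASD"}


@dataclass
class Clip:
    """One 1-second shot of cropped, patient-centered frames."""

    frames: np.ndarray          # (fps, side, side, 3) uint8
    patient_id: str
    label: str                  # "ASD" | "non-ASD"
    source_video: str = ""
    start_frame: int = 0

    def __post_init__(self):
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise ValueError(f"expected (F, H, W, 3) frames, got {self.frames.shape}")
        if self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("clip frames must be square")


@dataclass
class SampledClip:
    frames: np.ndarray          # (T, side, side, 3) uint8
    indices: np.ndarray         # the T sampled positions, strictly increasing
    patient_id: str
    label: str
    source_video: str = ""
    start_frame: int = 0


def slice_one_second_clips(frames: np.ndarray, patient_id: str, label: str,
                           fps: int = 30, source_video: str = "") -> list[Clip]:
    """Consecutive non-overlapping fps-frame windows; remainder dropped."""
    if fps < 1:
        raise ValueError("fps must be >= 1")
    n = len(frames) // fps
    return [
        Clip(frames=frames[i * fps:(i + 1) * fps], patient_id=patient_id,
             label=label, source_video=source_video, start_frame=i * fps)
        for i in range(n)
    ]


def uniform_indices(n_frames: int, t: int) -> np.ndarray:
    """Sampling positions floor(k * F / T) for k = 0..T-1."""
    if t > n_frames:
        raise ValueError(f"cannot sample {t} frames from {n_frames}")
    return (np.arange(t) * n_frames // t).astype(int)


def sample_frames(clip: Clip, t: int = 8) -> SampledClip:
    """Uniformly sample ``t`` frames from the clip (deterministic)."""
    idx = uniform_indices(len(clip.frames), t)
    return SampledClip(frames=clip.frames[idx], indices=idx,
                       patient_id=clip.patient_id, label=clip.label,
                       source_video=clip.source_video,
                       start_frame=clip.start_frame)


def resize_for_model(sampled: SampledClip, side: int = 224) -> np.ndarray:
    """Model input tensor (3, T, side, side), float32 in [0, 1].

    Frames must be square (the detection stage guarantees this); the
    resize is isotropic so nothing is distorted.
    """
    frames = sampled.frames
    if frames.shape[1] != frames.shape[2]:
        raise ValueError("model input requires square frames")
    resized = np.stack([_resize_isotropic(f, side) for f in frames])
    tensor = resized.astype(np.float32) / 255.0
    return np.ascontiguousarray(tensor.transpose(3, 0, 1, 2))


def short_side_scale_crop(frame: np.ndarray, side: int = 512) -> np.ndarray:
    """The no-detection preprocessing ablation: scale the shorter image
    side to ``side`` preserving aspect ratio, then center-crop a
    ``side`` x ``side`` square."""
    from skimage.transform import resize as sk_resize
    h, w = frame.shape[:2]
    scale = side / min(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    scaled = sk_resize(frame.astype(np.float64), (nh, nw), order=1,
                       anti_aliasing=scale < 1, preserve_range=True)
    scaled = np.clip(np.round(scaled), 0, 255).astype(np.uint8)
    y0 = (nh - side) // 2
    x0 = (nw - side) // 2
    return scaled[y0:y0 + side, x0:x0 + side]


@dataclass
class DatasetIndex:
    """Tabular index of prepared clips (one row per clip)."""

    records: list[dict] = field(default_factory=list)

    def add(self, clip_ref: str, patient_id: str, disease: str):
        if disease not in DISEASE_TO_LABEL:
            raise ValueError(f"unknown disease code {disease!r}")
        self.records.append({
            "clip": clip_ref, "patient_id": patient_id,
            "disease": disease, "label": DISEASE_TO_LABEL[disease],
        })

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.records,
                            columns=["clip", "patient_id", "disease", "label"])

    @classmethod
    def from_csv(cls, path) -> "DatasetIndex":
        import pandas as pd
        df = pd.read_csv(path)
        idx = cls()
        for _, row in df.iterrows():
            idx.add(row["clip"], row["patient_id"], row["disease"])
        return idx
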