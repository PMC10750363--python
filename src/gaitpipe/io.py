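"""Scene / clip I/O: PNG frame directories with JSON sidecars, cohort CSV.

Videos are exchanged as directories of numbered PNG frames (frame_0000.png
...), with the ground truth or track audit as a JSON sidecar next to them.
Cohort indices are plain CSV with columns (clip, patient_id, disease,
label).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np


def write_frames(frames: np.ndarray, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:04d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frames(in_dir) -> np.ndarray:
    paths = sorted(Path(in_dir).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {in_dir}")
    return np.stack([iio.imread(p) for p in paths])


def write_scene(scene, out_dir):
    """Scene frames as PNGs plus ground truth sidecar truth.json."""
    from .synthetic import truth_to_json
    out = Path(out_dir)
    write_frames(scene.frames, out)
    (out / "truth.json").write_text(truth_to_json(scene))


def write_json(obj, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
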