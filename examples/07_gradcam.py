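"""Grad-CAM++ attention maps for a clip, fused over time and overlaid."""

import numpy as np

from gaitpipe.cam import fuse_maps, gradcam_pp, overlay
from gaitpipe.clips import Clip, resize_for_model, sample_frames
from gaitpipe.detection import extract_patient_clip
from gaitpipe.nn import ArchitectureSpec, build_model
from gaitpipe.synthetic import SceneConfig, generate_scene, oracle_backend

scene = generate_scene(SceneConfig(n_frames=30, seed=5))
crops, _ = extract_patient_clip(scene.frames, oracle_backend(scene),
                                out_side=64)
clip = Clip(frames=crops, patient_id="P000", label="ASD")
x = resize_for_model(sample_frames(clip, 8), side=64)

model = build_model(ArchitectureSpec(block_counts=(1, 1, 1, 1),
                                     width_multiplier=0.25, input_side=64))
attn = gradcam_pp(model, x, target_class=0, layer="conv5_x")
print(f"attention maps: {attn.maps.shape}, range "
      f"[{attn.maps.min():.2f}, {attn.maps.max():.2f}]")
# One map per sampled frame (T=8), min-max normalized over the clip.

fused = fuse_maps(attn)          # pixelwise max across frames
print(f"fused map: {fused.shape}, peak {fused.max():.2f}")

img = overlay(fused, crops[15], alpha=0.5)
import imageio.v3 as iio
from pathlib import Path
Path("scratch").mkdir(exist_ok=True)
iio.imwrite("scratch/cam_overlay.png", img)
print("wrote scratch/cam_overlay.png "
      "(red = regions the model treats as evidence for class ASD)")
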