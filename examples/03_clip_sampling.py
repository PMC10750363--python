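"""Slice a cropped video into 1-second shots and sample 8 frames each."""

import numpy as np

from gaitpipe.clips import (resize_for_model, sample_frames,
                            slice_one_second_clips)

frames = np.zeros((75, 64, 64, 3), dtype=np.uint8)  # 2.5 s at 30 FPS
clips = slice_one_second_clips(frames, patient_id="P000", label="ASD")
print(f"{len(frames)} frames -> {len(clips)} clips "
      f"({len(frames) - 30 * len(clips)} trailing frames dropped)")

sampled = sample_frames(clips[0], t=8)
print(f"sampled indices: {sampled.indices.tolist()}")
# [0, 3, 7, 11, 15, 18, 22, 26]: floor(k * 30 / 8), the uniform stride
# sampling used for both training and testing.

x = resize_for_model(sampled, side=224)
print(f"model input tensor: {x.shape}, range [{x.min()}, {x.max()}]")
# (3, 8, 224, 224): channel-first, T=8 frames, values scaled to [0, 1].
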