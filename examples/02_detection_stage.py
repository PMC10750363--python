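"""Track the patient through a two-person scene and emit square crops.

The tracker initialises on the only person in frame 0 and then follows
the nearest body center; the trailing doctor never captures the track.
"""

from gaitpipe.detection import extract_patient_clip
from gaitpipe.synthetic import (MotionSignature, SceneConfig, generate_scene,
                                oracle_backend)

scene = generate_scene(SceneConfig(
    n_frames=40, seed=3,
    patient_signature=MotionSignature(stride_px=4.0),
    distractor_entry_frame=10, distractor_gap_px=60.0))

crops, track = extract_patient_clip(scene.frames, oracle_backend(scene),
                                    out_side=128)
print(f"crops: {crops.shape}  (one 128x128 RGB crop per input frame)")
print(f"carried-over frames: {track.gap_frames}")

correct = 0
for e in track.entries:
    tag = next(t for t, box, _ in scene.truth[e.frame_index]
               if box == e.detection.box)
    correct += tag == "patient"
print(f"tracked identity correct in {correct}/{len(track)} frames")
# 40/40: with the inter-person gap well above the per-frame stride the
# nearest-center rule provably cannot switch identity.
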