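import numpy as np
import pytest
from hypothesis import settings

from gaitpipe.synthetic import MotionSignature, SceneConfig, generate_scene

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def simple_scene():
    """Single walker, no distractor, 40 frames."""
    return generate_scene(SceneConfig(n_frames=40, seed=7))


@pytest.fixture(scope="session")
def distractor_scene():
    """Walker plus a second figure trailing from frame 10 onward."""
    cfg = SceneConfig(n_frames=40, seed=11, distractor_entry_frame=10,
                      distractor_gap_px=60.0,
                      patient_signature=MotionSignature(stride_px=4.0))
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def tiny_spec():
    from gaitpipe.nn import ArchitectureSpec
    return ArchitectureSpec(block_counts=(1, 1, 1, 1), width_multiplier=0.25,
                            input_side=64, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
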