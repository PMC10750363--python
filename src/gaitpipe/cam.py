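"""Gradient-weighted class-activation maps (Grad-CAM++) for the 3D
classifier, with temporal fusion into a single explanation image.

Per clip the map is computed at a chosen convolutional stage: channel
weights come from the positive partial derivatives of the target-class
logit with respect to the stage activations, using the second-order
closed form

    alpha_k = g_k^2 / (2 g_k^2 + sum(A_k) g_k^3),    w_k = sum(alpha_k * relu(g_k))

(sums over the stage's spatiotemporal positions).  The weighted
activation sum is rectified, upsampled to the frame resolution and
min-max normalized per clip, yielding one map per retained frame; the
per-frame maps are fused by pixelwise maximum (or mean) into a single
image, and can be alpha-blended as a colormap over a frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .nn import ResNet3d


@dataclass
class AttentionMap:
    maps: np.ndarray        # (T, H, W) in [0, 1]
    target_class: int
    layer: str

    def __post_init__(self):
        if self.maps.ndim != 3:
            raise ValueError("expected (T, H, W) maps")
        if self.maps.min() < 0 or self.maps.max() > 1:
            raise ValueError("maps must be min-max normalized to [0, 1]")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def gradcam_pp(model: ResNet3d, clip: np.ndarray, target_class: int,
               layer: str = "conv5_x", out_size: tuple[int, int] | None = None
               ) -> AttentionMap:
    """Grad-CAM++ attention maps for one clip.

    ``clip`` is a single model input (3, T, side, side) or (1, 3, T, side,
    side).  ``layer`` names a convolutional stage (conv1, conv2_x ..
    conv5_x).  Maps are upsampled (trilinear in space) to ``out_size``
    (default: the input frame size) and min-max normalized over the clip.
    Model weights carry no gradient state afterwards.
    """
    valid = ("conv1", "conv2_x", "conv3_x", "conv4_x", "conv5_x")
    if layer not in valid:
        raise ValueError(f"unknown layer {layer!r}; expected one of {valid}")
    x = clip[None] if clip.ndim == 4 else clip
    if x.shape[0] != 1:
        raise ValueError("one clip at a time")
    logits = model.forward(x.astype(np.float32), train=False, keep_cache=True,
                           capture_stage=layer)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target_class {target_class} out of range")
    activation = model.captured            # (1, C, t, h, w)
    dlogits = np.zeros_like(logits, dtype=np.float32)
    dlogits[0, target_class] = 1.0
    grad = model.backward(dlogits, stop_at_stage=layer)   # dlogit/dA
    model.zero_grads()
    model.clear_caches()

    a = activation[0].astype(np.float64)   # (C, t, h, w)
    g = grad[0].astype(np.float64)
    g2, g3 = g * g, g * g * g
    denom = 2.0 * g2 + a.sum(axis=(1, 2, 3), keepdims=True) * g3
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1, denom), 0.0)
    weights = (alpha * np.maximum(g, 0)).sum(axis=(1, 2, 3))   # (C,)
    cam = np.maximum((weights[:, None, None, None] * a).sum(axis=0), 0)  # (t,h,w)

    if out_size is None:
        out_size = (x.shape[3], x.shape[4])
    t = cam.shape[0]
    factors = (1, out_size[0] / cam.shape[1], out_size[1] / cam.shape[2])
    cam = zoom(cam, factors, order=1)
    cam = _minmax(cam)
    return AttentionMap(maps=cam, target_class=target_class, layer=layer)


def fuse_maps(m: AttentionMap, mode: str = "max") -> np.ndarray:
    """Collapse the T per-frame maps into one H x W map (max or mean)."""
    if mode == "max":
        return m.maps.max(axis=0)
    if mode == "mean":
        return m.maps.mean(axis=0)
    raise ValueError(f"unknown fusion mode {mode!r}")


def overlay(attn: np.ndarray, frame: np.ndarray, alpha: float = 0.5
            ) -> np.ndarray:
    """Alpha-blend a colormapped attention map onto an RGB frame.

    Red marks regions contributing positive evidence for the target
    class, blue regions contributing little.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if attn.shape != frame.shape[:2]:
        raise ValueError(f"map {attn.shape} does not match frame {frame.shape[:2]}")
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import cm as mpl_cm
    colored = (mpl_cm.jet(attn)[..., :3] * 255).astype(np.float64)
    blended = (1 - alpha) * frame.astype(np.float64) + alpha * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)
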