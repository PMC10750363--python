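"""Bottleneck-block residual 3D CNN for clip classification.

The architecture follows the standard 50-layer residual recipe lifted to
spatiotemporal inputs: a 3x7x7 stem with spatial stride 2, a 1x3x3 max
pool, four stages of bottleneck blocks (1x1x1 -> 3x3x3 -> 1x1x1 with a 4x
channel expansion), global spatiotemporal average pooling, and a fully
connected head whose outputs pass through an elementwise sigmoid.  All
temporal strides are 1, so the clip length T is preserved through every
convolutional stage; for a 224x224 input the stage spatial sizes are
112, 56, 56, 28, 14, 7.

At ``width_multiplier=1`` the pooled feature vector has 2048 entries.  A
``width_multiplier`` below 1 scales every channel count (the shape ladder
is unchanged), which makes exhaustive CPU testing of the full topology
practical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (BatchNorm3d, Conv3d, GlobalAvgPool, Linear, MaxPool3d,
                     ReLU, sigmoid)

#: inner (bottleneck) channels of the four stages at width 1
STAGE_INNER = (64, 128, 256, 512)
EXPANSION = 4


@dataclass
class ArchitectureSpec:
    """Structural description of the classifier.

    Defaults give the 50-layer network: block counts (3, 4, 6, 3), stem of
    64 3x7x7 filters with stride 1x2x2, and a 2-way sigmoid head.
    """

    block_counts: tuple[int, int, int, int] = (3, 4, 6, 3)
    n_classes: int = 2
    temporal_size: int = 8
    width_multiplier: float = 1.0
    input_side: int = 224
    seed: int = 0

    def __post_init__(self):
        if len(self.block_counts) != 4 or any(b < 1 for b in self.block_counts):
            raise ValueError("block_counts must be four integers >= 1")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")
        for c in STAGE_INNER:
            if (c * self.width_multiplier) != int(c * self.width_multiplier):
                raise ValueError(
                    f"width_multiplier {self.width_multiplier} does not divide "
                    f"the channel schedule {STAGE_INNER}")

    @property
    def feature_dim(self) -> int:
        """Length of the post-pool feature vector (2048 at width 1)."""
        return int(STAGE_INNER[-1] * EXPANSION * self.width_multiplier)

    def to_dict(self) -> dict:
        return {
            "block_counts": list(self.block_counts),
            "n_classes": self.n_classes,
            "temporal_size": self.temporal_size,
            "width_multiplier": self.width_multiplier,
            "input_side": self.input_side,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["block_counts"] = tuple(d["block_counts"])
        return cls(**d)


@dataclass
class Prediction:
    """Per-clip output: two independent sigmoid scores plus the argmax."""

    scores: np.ndarray          # (n_classes,) in [0, 1]
    predicted: int              # argmax class index
    positive_score: float       # score of the positive (ASD) class, index 0

    def __post_init__(self):
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("sigmoid scores must lie in [0, 1]")


class Bottleneck:
    """1x1x1 reduce -> 3x3x3 -> 1x1x1 expand, with identity/projection skip.

    Spatial downsampling (stride 1x2x2) sits on the 3x3x3 convolution of
    the first block of a stage; the skip then uses a strided 1x1x1
    projection.  Batch norm follows every convolution; the ReLU after the
    residual addition.
    """

    def __init__(self, c_in, c_inner, stride, rng):
        c_out = c_inner * EXPANSION
        self.conv1 = Conv3d(c_in, c_inner, 1, rng=rng)
        self.bn1 = BatchNorm3d(c_inner)
        self.conv2 = Conv3d(c_inner, c_inner, 3, stride=stride, pad=1, rng=rng)
        self.bn2 = BatchNorm3d(c_inner)
        self.conv3 = Conv3d(c_inner, c_out, 1, rng=rng)
        self.bn3 = BatchNorm3d(c_out)
        self.relu = ReLU()
        self._relu1 = ReLU()
        self._relu2 = ReLU()
        if c_in != c_out or stride != (1, 1, 1):
            self.proj = Conv3d(c_in, c_out, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm3d(c_out)
        else:
            self.proj = None

    def layers(self):
        ls = [self.conv1, self.bn1, self._relu1, self.conv2, self.bn2,
              self._relu2, self.conv3, self.bn3, self.relu]
        if self.proj is not None:
            ls += [self.proj, self.proj_bn]
        return ls

    def forward(self, x, train=False, keep_cache=True):
        out = self._relu1.forward(self.bn1.forward(self.conv1.forward(x, train, keep_cache),
                                                   train, keep_cache), train, keep_cache)
        out = self._relu2.forward(self.bn2.forward(self.conv2.forward(out, train, keep_cache),
                                                   train, keep_cache), train, keep_cache)
        out = self.bn3.forward(self.conv3.forward(out, train, keep_cache), train, keep_cache)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, train, keep_cache),
                                        train, keep_cache)
        else:
            skip = x
        return self.relu.forward(out + skip, train, keep_cache)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dskip = d
        d = self.conv3.backward(self.bn3.backward(d))
        d = self.conv2.backward(self.bn2.backward(self._relu2.backward(d)))
        d = self.conv1.backward(self.bn1.backward(self._relu1.backward(d)))
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(dskip))
        return d + dskip


class ResNet3d:
    """The assembled classifier.  Use :func:`build_model` to construct."""

    STAGE_NAMES = ("conv1", "pool1", "conv2_x", "conv3_x", "conv4_x", "conv5_x")

    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        w = spec.width_multiplier
        c_stem = int(64 * w)
        self.stem_conv = Conv3d(3, c_stem, (3, 7, 7), stride=(1, 2, 2), pad=(1, 3, 3), rng=rng)
        self.stem_bn = BatchNorm3d(c_stem)
        self.stem_relu = ReLU()
        self.pool1 = MaxPool3d((1, 3, 3), stride=(1, 2, 2), pad=(0, 1, 1))
        self.stages: list[list[Bottleneck]] = []
        c_in = c_stem
        for i, (inner, nblocks) in enumerate(zip(STAGE_INNER, spec.block_counts)):
            c_inner = int(inner * w)
            blocks = []
            for b in range(nblocks):
                stride = (1, 2, 2) if (i > 0 and b == 0) else (1, 1, 1)
                blocks.append(Bottleneck(c_in, c_inner, stride, rng))
                c_in = c_inner * EXPANSION
            self.stages.append(blocks)
        self.pool5 = GlobalAvgPool()
        self.fc = Linear(spec.feature_dim, spec.n_classes, rng=rng)

    # -- parameter plumbing -------------------------------------------------
    def _named_layers(self):
        yield "stem_conv", self.stem_conv
        yield "stem_bn", self.stem_bn
        for i, blocks in enumerate(self.stages):
            for b, blk in enumerate(blocks):
                for j, layer in enumerate(blk.layers()):
                    yield f"stage{i}.block{b}.layer{j}", layer
        yield "fc", self.fc

    def named_params(self):
        for lname, layer in self._named_layers():
            for pname, arr in layer.params.items():
                yield f"{lname}.{pname}", layer, pname, arr

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: arr.copy() for name, _, _, arr in self.named_params()}
        for lname, layer in self._named_layers():
            if isinstance(layer, BatchNorm3d):
                state[f"{lname}.running_mean"] = layer.running_mean.copy()
                state[f"{lname}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, layer, pname, arr in self.named_params():
            if name not in state:
                raise KeyError(f"missing parameter {name}")
            if state[name].shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {state[name].shape} "
                    f"vs model {arr.shape}")
            layer.params[pname] = state[name].astype(np.float32).copy()
        for lname, layer in self._named_layers():
            if isinstance(layer, BatchNorm3d):
                layer.running_mean = state[f"{lname}.running_mean"].astype(np.float32).copy()
                layer.running_var = state[f"{lname}.running_var"].astype(np.float32).copy()

    def clear_caches(self):
        for _, layer in self._named_layers():
            layer.clear_cache()
        self.pool1.clear_cache()
        self.pool5.clear_cache()

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x):
        if x.ndim != 5 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, T, H, W) input, got {x.shape}")

    def forward(self, x, *, train=False, keep_cache=None, capture_stage=None):
        """Full forward pass -> logits (N, n_classes).

        ``capture_stage`` names a stage (e.g. ``"conv5_x"``) whose output
        activation is stored on ``self.captured`` for attention mapping.
        """
        self._check_input(x)
        if keep_cache is None:
            keep_cache = train
        x = np.asarray(x, dtype=np.float32)
        self.captured = None
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train, keep_cache),
                                 train, keep_cache), train, keep_cache)
        if capture_stage == "conv1":
            self.captured = h
        h = self.pool1.forward(h, train, keep_cache)
        if capture_stage == "pool1":
            self.captured = h
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                h = blk.forward(h, train, keep_cache)
            if capture_stage == f"conv{i + 2}_x":
                self.captured = h
        feat = self.pool5.forward(h, train, keep_cache)
        self._last_feature = feat
        return self.fc.forward(feat, train, keep_cache)

    def backward(self, dlogits, *, stop_at_stage=None):
        """Backprop from the logits; returns the gradient arriving at
        ``stop_at_stage``'s output (or the input gradient if None)."""
        d = self.fc.backward(dlogits)
        d = self.pool5.backward(d)
        for i in range(len(self.stages) - 1, -1, -1):
            if stop_at_stage == f"conv{i + 2}_x":
                return d
            for blk in reversed(self.stages[i]):
                d = blk.backward(d)
        if stop_at_stage == "pool1":
            return d
        d = self.pool1.backward(d)
        if stop_at_stage == "conv1":
            return d
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        return self.stem_conv.backward(d)

    def zero_grads(self):
        for _, layer in self._named_layers():
            layer.grads = {}


def build_model(spec: ArchitectureSpec) -> ResNet3d:
    """Construct the classifier from its architecture description."""
    return ResNet3d(spec)


def forward(model: ResNet3d, batch: np.ndarray) -> list[Prediction]:
    """Evaluation-mode forward pass returning per-clip predictions."""
    logits = model.forward(batch, train=False, keep_cache=False)
    scores = sigmoid(logits)
    return [
        Prediction(scores=s, predicted=int(np.argmax(s)), positive_score=float(s[0]))
        for s in scores
    ]


def pooled_features(model: ResNet3d, batch: np.ndarray) -> np.ndarray:
    """Post-pool, pre-head feature vectors, shape (N, feature_dim)."""
    model.forward(batch, train=False, keep_cache=False)
    return model._last_feature


def adapt_head(model: ResNet3d, n_classes: int = 2, *, seed: int = 0) -> ResNet3d:
    """Replace the final fully connected layer with a fresh ``n_classes``-way
    one (transfer-learning head swap); every other weight is untouched."""
    d_in = model.fc.params["w"].shape[0]
    if d_in != model.spec.feature_dim:
        raise ValueError(
            f"feature-width mismatch: head expects {d_in}, "
            f"model produces {model.spec.feature_dim}")
    model.fc = Linear(d_in, n_classes, rng=np.random.default_rng(seed))
    model.spec.n_classes = n_classes
    return model


def save_checkpoint(model: ResNet3d, path):
    """Write weights + architecture to an .npz checkpoint."""
    state = model.state_dict()
    meta = model.spec.to_dict()
    np.savez(path, __meta__=np.array([repr(meta)], dtype=object), **state)


def load_checkpoint(path) -> ResNet3d:
    with np.load(path, allow_pickle=True) as z:
        meta = eval(z["__meta__"][0])  # repr of a plain dict written by us
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = build_model(ArchitectureSpec.from_dict(meta))
    model.load_state_dict(state)
    return model
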