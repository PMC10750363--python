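"""Adam optimizer over the model's named parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, model, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, layer, pname, arr in self.model.named_params():
            if pname not in layer.grads:
                continue
            g = layer.grads[pname].astype(np.float32)
            m = self.m.get(name)
            if m is None:
                m = np.zeros_like(arr)
                self.m[name] = m
                self.v[name] = np.zeros_like(arr)
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            layer.params[pname] = arr - self.lr * mhat / (np.sqrt(vhat) + self.eps)
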