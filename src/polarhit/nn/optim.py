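"""Adam optimizer over the layer parameter dictionaries."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, network, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 clip_norm=None, weight_decay=0.0):
        self.network = network
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.clip_norm = clip_norm
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {}
        self._v = {}
        for i, (layer, name) in enumerate(network.parameters()):
            self._m[i] = np.zeros_like(layer.params[name])
            self._v[i] = np.zeros_like(layer.params[name])

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        if self.clip_norm is not None:
            total = 0.0
            for layer, name in self.network.parameters():
                g = layer.grads.get(name)
                if g is not None:
                    total += float((g.astype(np.float64) ** 2).sum())
            norm = np.sqrt(total)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                for layer, name in self.network.parameters():
                    g = layer.grads.get(name)
                    if g is not None:
                        layer.grads[name] = g * g.dtype.type(scale)
        for i, (layer, name) in enumerate(self.network.parameters()):
            g = layer.grads.get(name)
            if g is None:
                continue
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self.t)
            vhat = self._v[i] / (1 - b2**self.t)
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and name not in ("b", "beta", "gamma"):
                # decoupled weight decay on weight matrices only
                step = step + self.lr * self.weight_decay * layer.params[name]
            layer.params[name] -= step
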