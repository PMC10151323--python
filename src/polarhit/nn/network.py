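"""The two-branch hitting-time network.

An image branch (two convolution blocks, each 3x3 convolution + batch
normalization + leaky ReLU + dropout + 2x2 max pooling, followed by a
512-node dense layer) and a clinical branch (32-node dense layer) are
concatenated and passed through a 256-node shared layer and one 256-node
layer per event; the per-event heads emit one logit per time bin and a
single softmax over all ``K x T`` cells turns the logits into a joint
probability mass over (cause, hitting time).  Event-free survival is the
mass not yet absorbed: ``S(t) = 1 - sum_k CIF_k(t)``.

The clinical-only variant drops the image branch entirely; the shared layer
then sees just the 32-dim clinical embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    MaxPool2,
)

__all__ = ["ArchitectureConfig", "DeepHitNetwork", "softmax_rows"]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Widths and regularization of the network."""

    n_events: int = 3
    n_bins: int = 131
    n_clinical: int = 15
    image_shape: tuple = (5, 28, 36)
    conv_channels: tuple = (16, 32)
    kernel: int = 3
    dropout: float = 0.3
    leaky_slope: float = 0.01
    image_dense_width: int = 512
    clinical_dense_width: int = 32
    shared_width: int = 256
    head_width: int = 256
    use_images: bool = True

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("n_events must be at least 1")
        for name in ("image_dense_width", "clinical_dense_width",
                     "shared_width", "head_width", "n_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DeepHitNetwork:
    """Seeded, deterministic forward/backward over the full architecture."""

    def __init__(self, arch: ArchitectureConfig, seed: int = 0, dtype=np.float32):
        self.arch = arch
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        a = arch
        self.image_layers = []
        concat_width = a.clinical_dense_width
        if a.use_images:
            c, h, w = a.image_shape
            chans = [c, *a.conv_channels]
            for blk, (ci, co) in enumerate(zip(chans[:-1], chans[1:])):
                self.image_layers += [
                    Conv2d(ci, co, a.kernel, rng=rng, dtype=dtype,
                           needs_input_grad=blk > 0),
                    BatchNorm2d(co, dtype=dtype),
                    LeakyReLU(a.leaky_slope),
                    Dropout(a.dropout),
                    MaxPool2(),
                ]
                h //= 2
                w //= 2
            flat = chans[-1] * h * w
            self.image_layers += [
                Flatten(),
                Dense(flat, a.image_dense_width, rng=rng, dtype=dtype),
                LeakyReLU(a.leaky_slope),
            ]
            concat_width += a.image_dense_width
        self.clinical_layers = [
            Dense(a.n_clinical, a.clinical_dense_width, rng=rng, dtype=dtype),
            LeakyReLU(a.leaky_slope),
        ]
        self.shared_layers = [
            Dense(concat_width, a.shared_width, rng=rng, dtype=dtype),
            LeakyReLU(a.leaky_slope),
        ]
        self.heads = []
        for _ in range(a.n_events):
            self.heads.append(
                [
                    Dense(a.shared_width, a.head_width, rng=rng, dtype=dtype),
                    LeakyReLU(a.leaky_slope),
                    Dense(a.head_width, a.n_bins, rng=rng, dtype=dtype),
                ]
            )

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        yield from self.image_layers
        yield from self.clinical_layers
        yield from self.shared_layers
        for head in self.heads:
            yield from head

    def parameters(self):
        """(layer, name) pairs for every trainable array."""
        for layer in self.layers():
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        ws = [layer.params[name].copy() for layer, name in self.parameters()]
        for layer in self.layers():
            if isinstance(layer, BatchNorm2d):
                ws += [layer.running_mean.copy(), layer.running_var.copy()]
        return ws

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer, name in self.parameters():
            layer.params[name] = next(it).copy()
        for layer in self.layers():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    # -- forward / backward -------------------------------------------------
    def forward(self, maps, clinical, *, train=False, rng=None):
        """Joint probability mass over (event, bin), shape (n, K, T).

        ``maps`` is the normalized (n, 5, 28, 36) stack (ignored when the
        architecture has no image branch); ``clinical`` the normalized
        (n, 15) matrix.
        """
        a = self.arch
        h_clin = np.asarray(clinical, dtype=self.dtype)
        for layer in self.clinical_layers:
            h_clin = layer.forward(h_clin, train=train, rng=rng)
        if a.use_images:
            if maps is None:
                raise ValueError("this architecture requires polar-map input")
            h_img = np.asarray(maps, dtype=self.dtype)
            if h_img.shape[1:] != a.image_shape:
                raise ValueError(
                    f"maps have shape {h_img.shape[1:]}, expected {a.image_shape}"
                )
            # image layers run channels-last for speed
            h_img = np.ascontiguousarray(h_img.transpose(0, 2, 3, 1))
            for layer in self.image_layers:
                h_img = layer.forward(h_img, train=train, rng=rng)
            h = np.concatenate([h_img, h_clin], axis=1)
            self._img_width = h_img.shape[1]
        else:
            h = h_clin
        for layer in self.shared_layers:
            h = layer.forward(h, train=train, rng=rng)
        logits = np.empty((h.shape[0], a.n_events, a.n_bins))
        for k, head in enumerate(self.heads):
            hk = h
            for layer in head:
                hk = layer.forward(hk, train=train, rng=rng)
            logits[:, k, :] = hk
        pmf_flat = softmax_rows(logits.reshape(h.shape[0], -1))
        self._pmf_flat = pmf_flat
        return pmf_flat.reshape(logits.shape)

    def backward(self, dpmf: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output pmf into layer grads."""
        n = dpmf.shape[0]
        g = dpmf.reshape(n, -1)
        y = self._pmf_flat
        dlogits = y * (g - (y * g).sum(axis=1, keepdims=True))
        dlogits = dlogits.reshape(n, self.arch.n_events, self.arch.n_bins)
        dshared = 0.0
        for k, head in enumerate(self.heads):
            gk = np.ascontiguousarray(dlogits[:, k, :], dtype=self.dtype)
            for layer in reversed(head):
                gk = layer.backward(gk)
            dshared = dshared + gk
        for layer in reversed(self.shared_layers):
            dshared = layer.backward(dshared)
        if self.arch.use_images:
            d_img = dshared[:, : self._img_width]
            d_clin = dshared[:, self._img_width :]
            for layer in reversed(self.image_layers):
                d_img = layer.backward(d_img)
        else:
            d_clin = dshared
        for layer in reversed(self.clinical_layers):
            d_clin = layer.backward(d_clin)
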