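"""The small convolutional classifier and its optimizer.

Architecture: repeated [3x3 conv -> ReLU -> 2x2 max pool] blocks, a global
average pooling (GAP) layer whose output is the image's latent embedding, a
ReLU dense layer, dropout, and a final dense layer read out through softmax
cross-entropy.  The backward pass is explicit, so the gradient of any class
logit with respect to the final convolutional activations is available for
Grad-CAM.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, Dense, Dropout, GlobalAvgPool, MaxPool2, ReLU


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Configurable conv-GAP-dense classifier on single-channel images."""

    def __init__(
        self,
        input_side: int,
        conv_widths,
        dense_units: int,
        dropout_rate: float,
        n_classes: int,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.input_side = int(input_side)
        self.n_classes = int(n_classes)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.layers = []
        c_in = 1
        for w in conv_widths:
            self.layers += [Conv2D(c_in, w, 3, rng, dtype), ReLU(), MaxPool2()]
            c_in = w
        # index of the final convolution's ReLU output (Grad-CAM target)
        self._last_conv_relu = len(self.layers) - 2
        self.layers.append(GlobalAvgPool())
        self._gap_index = len(self.layers) - 1
        self.embed_dim = c_in
        self.layers += [
            Dense(c_in, dense_units, rng, dtype),
            ReLU(),
            Dropout(dropout_rate, rng),
            Dense(dense_units, n_classes, rng, dtype),
        ]

    # -- plumbing -----------------------------------------------------------

    def _as_input(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        return x

    def forward(self, x, train: bool = False) -> np.ndarray:
        h = self._as_input(x)
        for layer in self.layers:
            h = layer.forward(h, train=train)
        return h

    def parameters(self):
        for layer in self.layers:
            for name, p in layer.params.items():
                yield layer, name, p

    def get_state(self) -> list:
        return [dict((k, v.copy()) for k, v in layer.params.items()) for layer in self.layers]

    def set_state(self, state) -> None:
        for layer, saved in zip(self.layers, state):
            for k in layer.params:
                layer.params[k][...] = saved[k]

    # -- training -----------------------------------------------------------

    def loss_and_grads(self, x, y_onehot, train: bool = True) -> float:
        logits = self.forward(x, train=train)
        probs = softmax(logits)
        n = len(logits)
        eps = 1e-12
        loss = float(-(y_onehot * np.log(probs + eps)).sum() / n)
        dlogits = ((probs - y_onehot) / n).astype(self.dtype)
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return loss

    def loss(self, x, y_onehot, batch: int = 256) -> float:
        """Cross-entropy without gradient bookkeeping (eval mode)."""
        total, n = 0.0, len(x)
        for i in range(0, n, batch):
            probs = self.predict_proba(x[i:i + batch])
            total += float(-(y_onehot[i:i + batch] * np.log(probs + 1e-12)).sum())
        return total / n

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def embed(self, x) -> np.ndarray:
        h = self._as_input(x)
        for layer in self.layers[: self._gap_index + 1]:
            h = layer.forward(h, train=False)
        return h

    def gradcam(self, x, target_class: int) -> np.ndarray:
        """Rectified class-activation maps for a batch, at final-conv resolution.

        Channel weights are the spatial means of d(logit)/d(activation);
        the map is the ReLU of the weighted channel sum.
        """
        if not 0 <= target_class < self.n_classes:
            raise ValueError(f"target_class {target_class} outside 0..{self.n_classes - 1}")
        h = self._as_input(x)
        acts = None
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train=False)
            if i == self._last_conv_relu:
                acts = h
        d = np.zeros_like(h)
        d[:, target_class] = 1.0
        for layer in reversed(self.layers[self._last_conv_relu + 1:]):
            d = layer.backward(d)
        alpha = d.mean(axis=(2, 3))  # (N, C) channel weights
        cam = np.einsum("nc,nchw->nhw", alpha, acts)
        return np.maximum(cam, 0.0)


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, net: SmallCNN, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self) -> None:
        self.t += 1
        for layer, name, p in self.net.parameters():
            g = layer.grads[name]
            key = (id(layer), name)
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
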