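"""A compact 1-D convolutional network for multi-label classification.

The architecture is fixed at nine layers: a 1-D convolution (10 filters,
kernel width 3, ReLU) over the feature vector treated as a length-n
sequence with one channel, max pooling (pool size and stride 2), a
flatten, and three (dropout 0.25, dense) pairs whose dense widths are 3C,
2C and C for C classes, the last with sigmoid activation.  Training
minimizes mean binary cross-entropy with Adam, so each output is an
independent per-class probability.

Implemented directly on numpy (forward and backward passes, inverted
dropout, Adam moments); everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TrainConfig:
    """Training budget and optimizer settings."""

    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 3e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ConvNet1D:
    """9-layer 1-D CNN: conv - pool - flatten - 3x(dropout, dense)."""

    FILTERS = 10
    KERNEL = 3
    POOL = 2
    DROPOUT = 0.25

    def __init__(self, n_features: int, n_classes: int, seed: int = 0):
        if n_features < self.KERNEL:
            raise ValueError(
                f"need at least {self.KERNEL} input features, got {n_features}"
            )
        if n_classes < 1:
            raise ValueError("need at least one class")
        self.n_features = n_features
        self.n_classes = n_classes
        self.rng = np.random.default_rng(seed)

        conv_len = n_features - self.KERNEL + 1
        self.pooled_len = conv_len // self.POOL
        if self.pooled_len < 1:
            raise ValueError("input too short for pooling")
        flat = self.pooled_len * self.FILTERS
        widths = (3 * n_classes, 2 * n_classes, n_classes)

        def he(fan_in: int, shape) -> np.ndarray:
            return self.rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.Wc = he(self.KERNEL, (self.KERNEL, self.FILTERS))
        self.bc = np.zeros(self.FILTERS)
        self.W = []
        self.b = []
        fan = flat
        for w in widths:
            self.W.append(he(fan, (fan, w)))
            self.b.append(np.zeros(w))
            fan = w
        self._adam_state = None

    # -- architecture ------------------------------------------------------

    def architecture_audit(self) -> list[dict]:
        """Ordered layer descriptors for auditing against the fixed spec."""
        c = self.n_classes
        return [
            {"layer": "conv1d", "filters": self.FILTERS, "kernel": self.KERNEL,
             "activation": "relu"},
            {"layer": "maxpool1d", "pool": self.POOL, "stride": self.POOL},
            {"layer": "flatten"},
            {"layer": "dropout", "rate": self.DROPOUT},
            {"layer": "dense", "units": 3 * c, "activation": "relu"},
            {"layer": "dropout", "rate": self.DROPOUT},
            {"layer": "dense", "units": 2 * c, "activation": "relu"},
            {"layer": "dropout", "rate": self.DROPOUT},
            {"layer": "dense", "units": c, "activation": "sigmoid"},
        ]

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool):
        cache: dict = {}
        windows = np.lib.stride_tricks.sliding_window_view(X, self.KERNEL, axis=1)
        z = windows @ self.Wc + self.bc  # (N, L-2, F)
        a = np.maximum(z, 0.0)
        cache["windows"], cache["conv_pre"] = windows, z

        n, m, f = a.shape
        p = self.pooled_len
        blocks = a[:, : 2 * p].reshape(n, p, self.POOL, f)
        arg = blocks.argmax(axis=2)
        pooled = blocks.max(axis=2)
        cache["pool_arg"], cache["pool_shape"] = arg, (n, m, f)

        h = pooled.reshape(n, -1)
        activations = []
        masks = []
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            if train:
                mask = (self.rng.random(h.shape) >= self.DROPOUT) / (1 - self.DROPOUT)
            else:
                mask = np.ones_like(h)
            h = h * mask
            masks.append(mask)
            z = h @ W + b
            if i < len(self.W) - 1:
                a_i = np.maximum(z, 0.0)
            else:
                a_i = _sigmoid(z)
            activations.append((h, z, a_i))
            h = a_i
        cache["dense"] = activations
        cache["masks"] = masks
        return h, cache

    def _backward(self, Y: np.ndarray, cache: dict) -> list[np.ndarray]:
        grads_W, grads_b = [], []
        activations = cache["dense"]
        n = Y.shape[0]
        # sigmoid + BCE: dL/dz = (p - y) / (n * C)
        _, _, p = activations[-1]
        delta = (p - Y) / (n * self.n_classes)
        for i in reversed(range(len(self.W))):
            h_in, z, _ = activations[i]
            grads_W.insert(0, h_in.T @ delta)
            grads_b.insert(0, delta.sum(axis=0))
            delta = (delta @ self.W[i].T) * cache["masks"][i]
            if i > 0:
                _, z_prev, _ = activations[i - 1]
                delta = delta * (z_prev > 0)
        # through flatten and pooling to the conv layer
        nb, m, f = cache["pool_shape"]
        pgrad = delta.reshape(nb, self.pooled_len, f)
        conv_grad = np.zeros((nb, m, f))
        arg = cache["pool_arg"]
        rows = np.arange(nb)[:, None, None]
        cols = (np.arange(self.pooled_len) * self.POOL)[None, :, None] + arg
        filt = np.arange(f)[None, None, :]
        np.add.at(conv_grad, (rows, cols, filt), pgrad)
        conv_grad = conv_grad * (cache["conv_pre"] > 0)
        dWc = np.einsum("nlw,nlf->wf", cache["windows"], conv_grad)
        dbc = conv_grad.sum(axis=(0, 1))
        return [dWc, dbc] + [g for pair in zip(grads_W, grads_b) for g in pair]

    def _params(self) -> list[np.ndarray]:
        out = [self.Wc, self.bc]
        for W, b in zip(self.W, self.b):
            out.extend([W, b])
        return out

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray, config: TrainConfig | None = None):
        """Train with Adam on mean binary cross-entropy."""
        cfg = config or TrainConfig()
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        params = self._params()
        m_state = [np.zeros_like(p) for p in params]
        v_state = [np.zeros_like(p) for p in params]
        t = 0
        n = len(X)
        for _ in range(cfg.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                _, cache = self._forward(X[idx], train=True)
                grads = self._backward(Y[idx], cache)
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**t) / (1 - cfg.beta1**t)
                for p, g, m, v in zip(params, grads, m_state, v_state):
                    m *= cfg.beta1
                    m += (1 - cfg.beta1) * g
                    v *= cfg.beta2
                    v += (1 - cfg.beta2) * g * g
                    p -= lr_t * m / (np.sqrt(v) + cfg.eps)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Independent per-class probabilities in (0, 1)."""
        out, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return out

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def verify_architecture(model: ConvNet1D) -> dict:
    """Audit the model against the fixed nine-layer specification.

    Returns a summary dict; raises ``AssertionError`` on any deviation.
    """
    audit = model.architecture_audit()
    c = model.n_classes
    assert len(audit) == 9, f"expected 9 layers, audit lists {len(audit)}"
    kinds = [a["layer"] for a in audit]
    assert kinds == [
        "conv1d", "maxpool1d", "flatten",
        "dropout", "dense", "dropout", "dense", "dropout", "dense",
    ], f"unexpected layer order {kinds}"
    assert audit[0]["filters"] == 10 and audit[0]["kernel"] == 3
    assert audit[1]["pool"] == 2 and audit[1]["stride"] == 2
    dense_units = [a["units"] for a in audit if a["layer"] == "dense"]
    assert dense_units == [3 * c, 2 * c, c], f"dense widths {dense_units}"
    dropouts = {a["rate"] for a in audit if a["layer"] == "dropout"}
    assert dropouts == {0.25}, f"dropout rates {dropouts}"
    assert audit[-1]["activation"] == "sigmoid"
    # the live parameter shapes must agree with the audit
    assert model.Wc.shape == (3, 10)
    assert [W.shape[1] for W in model.W] == dense_units
    return {
        "n_layers": len(audit),
        "dense_units": dense_units,
        "dropout": 0.25,
        "final_activation": "sigmoid",
        "layers": audit,
    }
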