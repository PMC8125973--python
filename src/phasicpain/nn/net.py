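"""Containers, output heads, losses and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Dense, Layer, Param


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy of integer targets; returns (loss, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), targets] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


class Sequential(Layer):
    """A chain of layers applied in order."""

    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    @params.setter
    def params(self, value):  # Layer.__init__ compatibility
        pass

    def initialize(self, rng):
        for layer in self.layers:
            layer.initialize(rng)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Residual(Layer):
    """y = f(x) + x around an inner sequential block (shapes must match)."""

    def __init__(self, inner: Sequential):
        super().__init__()
        self.inner = inner

    @property
    def params(self):
        return self.inner.params

    @params.setter
    def params(self, value):
        pass

    def initialize(self, rng):
        self.inner.initialize(rng)

    def forward(self, x, train=False):
        return self.inner.forward(x, train=train) + x

    def backward(self, dout):
        return self.inner.backward(dout) + dout


class Head:
    """One output layer: a dense projection plus its activation/loss kind.

    ``kind`` is ``softmax`` (classification, cross-entropy), ``linear``
    (scalar regression, squared error) or ``sigmoid`` (scalar in (0, 1),
    cross-entropy).
    """

    def __init__(self, in_features: int, width: int, kind: str, name: str = ""):
        if kind not in ("softmax", "linear", "sigmoid"):
            raise ValueError(f"unknown head kind {kind!r}")
        if kind in ("linear", "sigmoid") and width != 1:
            raise ValueError(f"{kind} head must have width 1")
        self.dense = Dense(in_features, width)
        self.kind = kind
        self.width = width
        self.name = name or kind

    def activate(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "softmax":
            return softmax(z)
        if self.kind == "sigmoid":
            return sigmoid(z)
        return z

    def loss_grad(self, z: np.ndarray, target: np.ndarray):
        n = z.shape[0]
        if self.kind == "softmax":
            return softmax_cross_entropy(z, np.asarray(target, dtype=int))
        t = np.asarray(target, dtype=float).reshape(n, 1)
        if self.kind == "linear":
            diff = z - t
            return float(np.mean(diff**2)), 2.0 * diff / n
        p = sigmoid(z)
        eps = 1e-12
        loss = float(-np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))
        return loss, (p - t) / n


class FusionNet:
    """Two feature branches, a shared dense trunk, and one or more heads.

    Branch outputs are concatenated and passed through the trunk; every
    head reads the trunk's top features.  With one softmax head this is a
    plain classifier; with a modality head plus an intensity head it is the
    multi-task variant.
    """

    def __init__(self, branches: list[Sequential], trunk: Sequential,
                 heads: list[Head], branch_widths: list[int]):
        self.branches = branches
        self.trunk = trunk
        self.heads = heads
        self.branch_widths = branch_widths

    def parameters(self) -> list[Param]:
        params = []
        for b in self.branches:
            params.extend(b.params)
        params.extend(self.trunk.params)
        for h in self.heads:
            params.extend(h.dense.params)
        return params

    def initialize(self, seed: int):
        rng = np.random.default_rng(seed)
        for b in self.branches:
            b.initialize(rng)
        self.trunk.initialize(rng)
        for h in self.heads:
            h.dense.initialize(rng)

    def forward(self, inputs: list[np.ndarray], train=False) -> list[np.ndarray]:
        """Raw head outputs (pre-activation) for a list of branch inputs."""
        feats = [b.forward(x, train=train) for b, x in zip(self.branches, inputs)]
        fused = np.concatenate(feats, axis=1)
        top = self.trunk.forward(fused, train=train)
        return [h.dense.forward(top, train=train) for h in self.heads]

    def predict(self, inputs: list[np.ndarray]) -> list[np.ndarray]:
        """Activated head outputs in eval mode."""
        zs = self.forward(inputs, train=False)
        return [h.activate(z) for h, z in zip(self.heads, zs)]

    def backward_from_heads(self, dzs: list[np.ndarray]) -> None:
        dtop = sum(h.dense.backward(dz) for h, dz in zip(self.heads, dzs))
        dfused = self.trunk.backward(dtop)
        start = 0
        for b, width in zip(self.branches, self.branch_widths):
            b.backward(dfused[:, start:start + width])
            start += width

    def train_step(self, inputs, targets, optimizer) -> float:
        """One forward/backward/update pass; returns the summed head loss."""
        for p in self.parameters():
            p.grad[...] = 0.0
        zs = self.forward(inputs, train=True)
        total = 0.0
        dzs = []
        for h, z, t in zip(self.heads, zs, targets):
            loss, dz = h.loss_grad(z, t)
            total += loss
            dzs.append(dz)
        self.backward_from_heads(dzs)
        optimizer.step()
        return float(total)


class Adam:
    """Adam optimizer over a list of :class:`Param` objects."""

    def __init__(self, params: list[Param], lr=1e-4, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
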