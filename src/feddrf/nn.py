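"""Minimal numpy neural-network core with manual backpropagation.

Provides exactly the layers the federated models need: dense, valid 2D
convolution (im2col), elementwise activations, flatten, and a two-arm
architecture that processes a cell image and a drug image through
separate convolutional stacks before a shared dense trunk and a linear
head.  Parameters live in flat ``{name: ndarray}`` dicts so federated
averaging can treat every model identically.  All initialisation and
shuffling is driven by explicit numpy Generators; given the same seed,
data and config, training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv2D", "Activation", "Flatten", "Sequential", "TwoArmNet", "SGD"]


class Layer:
    """Forward/backward protocol; parameters and gradients as name->array."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def forward(self, x):  # caches what backward needs
        raise NotImplementedError

    def backward(self, gout):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.gW = self._x.T @ gout
        self.gb = gout.sum(axis=0)
        return gout @ self.W.T


class Conv2D(Layer):
    """Valid cross-correlation, stride 1, square kernel; input (B, C, H, W)."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        fan_in = in_ch * ksize * ksize
        limit = np.sqrt(6.0 / (fan_in + out_ch))
        self.W = rng.uniform(-limit, limit, size=(out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch)
        self.k = ksize
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.gW, "b": self.gb}

    def _im2col(self, x):
        B, C, H, Wd = x.shape
        k = self.k
        oh, ow = H - k + 1, Wd - k + 1
        shape = (B, C, oh, ow, k, k)
        strides = x.strides[:2] + x.strides[2:] + x.strides[2:]
        patches = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
        # (B, oh, ow, C*k*k)
        return patches.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh, ow, C * k * k), (oh, ow)

    def forward(self, x):
        self._xshape = x.shape
        cols, (oh, ow) = self._im2col(np.ascontiguousarray(x))
        self._cols = cols
        Wmat = self.W.reshape(self.W.shape[0], -1)  # (F, C*k*k)
        out = cols @ Wmat.T + self.b  # (B, oh, ow, F)
        return out.transpose(0, 3, 1, 2)

    def backward(self, gout):
        B, F, oh, ow = gout.shape
        g = gout.transpose(0, 2, 3, 1).reshape(-1, F)  # (B*oh*ow, F)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.gW = (g.T @ cols).reshape(self.W.shape)
        self.gb = g.sum(axis=0)
        Wmat = self.W.reshape(F, -1)
        gcols = (g @ Wmat).reshape(B, oh, ow, -1)
        # scatter-add column gradients back onto the input
        _, C, H, Wd = self._xshape
        k = self.k
        gx = np.zeros(self._xshape)
        gcols = gcols.reshape(B, oh, ow, C, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + oh, dj : dj + ow] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx


class Activation(Layer):
    def __init__(self, kind: str):
        if kind not in ("relu", "tanh", "sigmoid"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x):
        if self.kind == "relu":
            self._y = np.maximum(x, 0.0)
        elif self.kind == "tanh":
            self._y = np.tanh(x)
        else:
            self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gout):
        if self.kind == "relu":
            return gout * (self._y > 0)
        if self.kind == "tanh":
            return gout * (1.0 - self._y**2)
        return gout * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"{i}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"{i}.{k}"] = v
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout):
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout


class TwoArmNet:
    """Two convolutional arms (cell image, drug image) -> dense trunk -> linear head.

    ``forward`` takes a dict of inputs.  For flat (non-image) models pass
    a single arm named "flat" whose stack is just ``Flatten``-free dense
    layers.  The head is the final linear layer; in personalized
    federation it is the layer excluded from aggregation.
    """

    def __init__(self, arms: dict, trunk: Sequential, head: Dense):
        self.arms = arms  # name -> Sequential
        self.trunk = trunk
        self.head = head

    def _pieces(self):
        pieces = [(f"arm:{name}", arm) for name, arm in sorted(self.arms.items())]
        pieces.append(("trunk", self.trunk))
        pieces.append(("head", self.head))
        return pieces

    def params(self) -> dict:
        out = {}
        for prefix, piece in self._pieces():
            for k, v in piece.params().items():
                out[f"{prefix}.{k}"] = v
        return out

    def grads(self) -> dict:
        out = {}
        for prefix, piece in self._pieces():
            for k, v in piece.grads().items():
                out[f"{prefix}.{k}"] = v
        return out

    def set_params(self, params: dict) -> None:
        own = self.params()
        missing = set(own) - set(params)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        for k, v in own.items():
            if params[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: {params[k].shape} vs {v.shape}")
            v[...] = params[k]

    def forward(self, inputs: dict) -> np.ndarray:
        outs = []
        self._split = []
        for name in sorted(self.arms):
            z = self.arms[name].forward(inputs[name])
            outs.append(z)
            self._split.append(z.shape[1])
        h = np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]
        h = self.trunk.forward(h)
        return self.head.forward(h)

    def backward(self, gout) -> None:
        g = self.trunk.backward(self.head.backward(gout))
        offset = 0
        for name, width in zip(sorted(self.arms), self._split):
            self.arms[name].backward(g[:, offset : offset + width])
            offset += width


class SGD:
    """Plain SGD with optional momentum; deterministic given data order."""

    def __init__(self, lr: float, momentum: float = 0.0):
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        for k, p in params.items():
            g = grads[k]
            if self.momentum > 0.0:
                v = self._velocity.get(k)
                if v is None:
                    v = np.zeros_like(p)
                v = self.momentum * v - self.lr * g
                self._velocity[k] = v
                p += v
            else:
                p -= self.lr * g
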