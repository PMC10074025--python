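"""Federated-ready regression models sharing one parameter-dict surface.

Three model families mirror the study design:

* ``ann`` — dense network on the flat concatenated feature vector;
* ``refined_cnn`` — two-arm CNN on REFINED cell/drug images with a
  scalar regression head trained on squared error;
* ``refined_drf`` — the same two-arm extractor whose head emits one
  logit per internal tree node of a Deep Regression Forest.

Every model exposes ``get_params``/``set_params`` over flat name->array
dicts (the DRF leaves ride along as ``forest.mu``/``forest.var``), one
deterministic ``train_epoch`` and ``predict``, which is all the
federation core needs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .drf import (
    TreeTopology,
    VARIANCE_FLOOR,
    drf_nll_grad_s,
    forest_nll,
    init_leaves,
    routing_probabilities,
    tree_predict,
    update_forest_leaves,
)
from .metrics import nrmse

__all__ = ["ModelConfig", "Dataset", "MSERegressor", "DRFRegressor", "build_model", "child_rng"]


def child_rng(*keys: int) -> np.random.Generator:
    """Deterministic child generator from integer keys (seed, round, client...)."""
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in keys]))


@dataclass
class Dataset:
    """In-memory batch of model inputs plus targets.

    ``inputs`` maps arm names to arrays with leading sample dimension:
    image arms are (n, 1, g, g); the flat arm is (n, p).
    """

    inputs: dict
    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        for k, v in self.inputs.items():
            if v.shape[0] != self.y.size:
                raise ValueError(f"input {k!r} has {v.shape[0]} rows but y has {self.y.size}")

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset({k: v[idx] for k, v in self.inputs.items()}, self.y[idx])

    def batches(self, batch_size: int, rng: np.random.Generator):
        order = rng.permutation(self.n)
        for start in range(0, self.n, batch_size):
            yield self.subset(order[start : start + batch_size])


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    ``conv_filters`` is the per-arm convolution stack (empty tuple means
    dense-only arms); ``hidden`` the trunk widths.  The client-baseline
    preset (``reduced()``) drops the last convolution per arm, keeps a
    single hidden layer and shrinks the batch to 12, matching how the
    individually trained client models are slimmed down.
    """

    kind: str = "refined_drf"  # ann | refined_cnn | refined_drf
    conv_filters: tuple = (4,)
    ksize: int = 3
    hidden: tuple = (32, 16)
    trees: int = 2
    depth: int = 4
    leaf_update_iters: int = 3
    variance_floor: float = VARIANCE_FLOOR
    lr: float = 0.05
    momentum: float = 0.9
    batch_size: int = 32

    def reduced(self) -> "ModelConfig":
        return replace(
            self,
            conv_filters=self.conv_filters[:-1],
            hidden=self.hidden[:1],
            batch_size=12,
        )


def _conv_out_side(side: int, n_layers: int, ksize: int) -> int:
    for _ in range(n_layers):
        side = side - ksize + 1
        if side < 1:
            raise ValueError("image too small for the convolution stack")
    return side


def _build_arm(shape, config: ModelConfig, rng) -> tuple[nn.Sequential, int]:
    if len(shape) == 1:  # flat arm: identity, trunk does the work
        return nn.Sequential([]), shape[0]
    ch, h, w = shape
    layers = []
    for f in config.conv_filters:
        layers += [nn.Conv2D(ch, f, config.ksize, rng), nn.Activation("relu")]
        ch = f
        h, w = h - config.ksize + 1, w - config.ksize + 1
        if h < 1 or w < 1:
            raise ValueError("image too small for the convolution stack")
    layers.append(nn.Flatten())
    return nn.Sequential(layers), ch * h * w


def _build_net(input_spec: dict, config: ModelConfig, out_dim: int, seed: int) -> nn.TwoArmNet:
    rng = child_rng(seed, 0xA11)
    arms, width = {}, 0
    for name in sorted(input_spec):
        arm, w = _build_arm(tuple(input_spec[name]), config, rng)
        arms[name] = arm
        width += w
    trunk_layers = []
    for hdim in config.hidden:
        trunk_layers += [nn.Dense(width, hdim, rng), nn.Activation("tanh")]
        width = hdim
    trunk = nn.Sequential(trunk_layers)
    head = nn.Dense(width, out_dim, rng)
    return nn.TwoArmNet(arms, trunk, head)


class _ModelBase:
    """Shared parameter plumbing and the deterministic training epoch."""

    def __init__(self, config: ModelConfig, input_spec: dict, seed: int, out_dim: int):
        self.config = config
        self.input_spec = dict(input_spec)
        self.net = _build_net(input_spec, config, out_dim, seed)

    # -- parameter surface -------------------------------------------------
    def get_params(self) -> dict:
        return {k: v.copy() for k, v in self.net.params().items()}

    def set_params(self, params: dict) -> None:
        self.net.set_params(params)

    def clone(self) -> "_ModelBase":
        return copy.deepcopy(self)

    # -- training ----------------------------------------------------------
    def _loss_grad(self, batch: Dataset):
        raise NotImplementedError

    def _post_epoch(self, data: Dataset) -> None:
        pass

    def train_epoch(self, data: Dataset, rng: np.random.Generator, lr: float | None = None):
        """One pass of mini-batch SGD (fresh optimiser state each epoch)."""
        opt = nn.SGD(lr=self.config.lr if lr is None else lr, momentum=self.config.momentum)
        for batch in data.batches(self.config.batch_size, rng):
            loss, gz = self._loss_grad(batch)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss: {loss}")
            self.net.backward(gz)
            opt.step(self.net.params(), self.net.grads())
        self._post_epoch(data)

    def predict(self, data: Dataset) -> np.ndarray:
        raise NotImplementedError

    def val_nrmse(self, data: Dataset) -> float:
        return nrmse(data.y, self.predict(data))


class MSERegressor(_ModelBase):
    """Scalar-head network trained on mean squared error (ANN / REFINED-CNN)."""

    def __init__(self, config: ModelConfig, input_spec: dict, seed: int = 0):
        super().__init__(config, input_spec, seed, out_dim=1)

    def _loss_grad(self, batch: Dataset):
        z = self.net.forward(batch.inputs).ravel()
        resid = z - batch.y
        loss = 0.5 * float(np.mean(resid**2))
        return loss, (resid / batch.n).reshape(-1, 1)

    def predict(self, data: Dataset) -> np.ndarray:
        return self.net.forward(data.inputs).ravel()


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class DRFRegressor(_ModelBase):
    """Two-arm extractor routing a forest of Gaussian-leaf regression trees."""

    def __init__(self, config: ModelConfig, input_spec: dict, seed: int = 0):
        self.topology = TreeTopology(config.depth)
        super().__init__(config, input_spec, seed,
                         out_dim=self.topology.n_outputs(config.trees))
        self.leaves = init_leaves(self.topology, config.trees)

    # leaves are federated parameters like any network tensor
    def get_params(self) -> dict:
        params = super().get_params()
        params["forest.mu"] = self.leaves.mu.copy()
        params["forest.var"] = self.leaves.var.copy()
        return params

    def set_params(self, params: dict) -> None:
        net_params = {k: v for k, v in params.items() if not k.startswith("forest.")}
        self.net.set_params(net_params)
        self.leaves.mu[...] = params["forest.mu"]
        self.leaves.var[...] = np.maximum(params["forest.var"], self.config.variance_floor)

    def _routing(self, inputs: dict) -> np.ndarray:
        return _sigmoid(self.net.forward(inputs))

    def _loss_grad(self, batch: Dataset):
        z = self.net.forward(batch.inputs)
        s = _sigmoid(z)
        loss, gs = drf_nll_grad_s(batch.y, s, self.topology, self.leaves)
        return loss, gs * s * (1.0 - s)

    def _post_epoch(self, data: Dataset) -> None:
        # network frozen: closed-form responsibility update of the leaves
        s = self._routing(data.inputs)
        self.leaves = update_forest_leaves(
            data.y, s, self.topology, self.leaves,
            n_iter=self.config.leaf_update_iters, floor=self.config.variance_floor,
        )

    def predict(self, data: Dataset) -> np.ndarray:
        s = self._routing(data.inputs)
        N = self.topology.n_internal
        preds = []
        for t in range(self.config.trees):
            P = routing_probabilities(s[:, t * N : (t + 1) * N], self.topology)
            preds.append(tree_predict(P, self.leaves.mu[t]))
        return np.mean(preds, axis=0)

    def nll(self, data: Dataset) -> float:
        return forest_nll(data.y, self._routing(data.inputs), self.topology, self.leaves)


def build_model(config: ModelConfig, input_spec: dict, seed: int = 0) -> _ModelBase:
    """Instantiate a model of ``config.kind`` for the given input shapes."""
    if config.kind == "refined_drf":
        return DRFRegressor(config, input_spec, seed)
    if config.kind in ("refined_cnn", "ann"):
        return MSERegressor(config, input_spec, seed)
    raise ValueError(f"unknown model kind {config.kind!r}")
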