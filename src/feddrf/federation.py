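"""Cross-silo horizontal federated averaging over the model-parameter surface.

One server and n institutional clients.  The server pretrains an initial
model on its own small proxy set DT(I), then repeats for up to M rounds:
broadcast the global parameters; every client runs exactly one epoch of
local backpropagation followed by one leaf-update pass (DRF) on its
private shard; the server scores each client's updated model on the
validation set DV *before* aggregation (these per-client loss
trajectories feed the heterogeneity diagnostic), then forms the new
global model as the data-weighted average of every network tensor and
every leaf mean/variance.  Learning-rate reduction and early stopping
act on the aggregated model's DV loss.

Only parameter arrays, sample counts and counter integers ever cross the
client boundary — ``ClientUpdate`` has no raw-data field.

In the personalized variant the final (head) layer is excluded from
aggregation: each client keeps its own head, and the stopping/LR
counters are the mean of the per-client counters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Dataset, child_rng

__all__ = [
    "FedConfig",
    "ClientUpdate",
    "FederationResult",
    "aggregation_weights",
    "federated_average",
    "client_update",
    "pretrain_server",
    "fit_centralized",
    "run_federation",
]

_EPOCH_TAG = 0xE0  # rng stream tag shared by federated and centralized epochs
PERSONAL_PREFIX = "head."


@dataclass(frozen=True)
class FedConfig:
    """Federation loop settings.

    ``patience`` (rounds without DV improvement before stopping) and the
    LR plateau schedule are tool defaults; ``mode`` is ``standard`` or
    ``personalized``.
    """

    rounds: int = 50
    lr: float | None = None  # None: use the model's configured rate
    patience: int = 10
    lr_patience: int = 5
    lr_factor: float = 0.5
    mode: str = "standard"

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.mode not in ("standard", "personalized"):
            raise ValueError(f"unknown federation mode {self.mode!r}")


@dataclass(frozen=True)
class ClientUpdate:
    """The only artifact a client sends back: parameters and counts."""

    params: dict
    n_samples: int
    non_improving_epochs: int = 0


@dataclass
class FederationResult:
    model: object
    log: pd.DataFrame
    rounds_run: int
    client_params: list = field(default_factory=list)  # final per-client params

    def client_trajectories(self) -> np.ndarray:
        wide = self.log.pivot_table(index="client_id", columns="round", values="val_nrmse")
        return wide.to_numpy()


def aggregation_weights(counts) -> np.ndarray:
    """Normalised non-negative weights, by default client sample counts."""
    w = np.asarray(counts, dtype=float)
    if (w < 0).any():
        raise ValueError("negative aggregation weight")
    total = w.sum()
    if total <= 0:
        raise ValueError("all aggregation weights are zero")
    return w / total


def federated_average(updates, weights, variance_floor: float = 1e-4) -> dict:
    """Element-wise weighted mean of every parameter tensor.

    Covers network tensors and the DRF leaf arrays alike; aggregated leaf
    variances are re-floored.  All parameter sets must share names/shapes.
    """
    weights = np.asarray(weights, dtype=float)
    if len(updates) != len(weights):
        raise ValueError("one weight per update required")
    if len(updates) == 0:
        raise ValueError("no updates to aggregate")
    names = list(updates[0])
    for upd in updates[1:]:
        if set(upd) != set(names):
            raise ValueError("parameter name mismatch across clients")
    out = {}
    for k in names:
        ref = updates[0][k]
        for upd in updates[1:]:
            if upd[k].shape != ref.shape:
                raise ValueError(f"shape mismatch for tensor {k!r}")
        acc = np.zeros_like(ref, dtype=float)
        for w, upd in zip(weights, updates):
            acc += w * upd[k]
        if k == "forest.var":
            acc = np.maximum(acc, variance_floor)
        out[k] = acc
    return out


def client_update(model, global_params: dict, data: Dataset,
                  rng: np.random.Generator, lr: float) -> ClientUpdate:
    """One client round: initialise from the broadcast, train one epoch locally.

    ``model`` is a private workspace clone.  Exactly one epoch of
    backpropagation runs (followed, for DRF models, by the leaf-update
    pass); the return value carries only parameters and counts.
    """
    if data.n == 0:
        warnings.warn("client has no data: skipped with weight 0", stacklevel=2)
        return ClientUpdate(params=dict(global_params), n_samples=0)
    model.set_params(global_params)
    model.train_epoch(data, rng, lr=lr)
    return ClientUpdate(params=model.get_params(), n_samples=data.n)


class _Plateau:
    """Best-so-far tracker driving LR reduction and early stopping."""

    def __init__(self, patience: int, lr_patience: int):
        self.best = np.inf
        self.since_best = 0
        self.since_lr = 0
        self.patience = patience
        self.lr_patience = lr_patience

    def update(self, loss: float) -> dict:
        if loss < self.best:
            self.best = loss
            self.since_best = 0
            self.since_lr = 0
        else:
            self.since_best += 1
            self.since_lr += 1
        reduce_lr = self.since_lr >= self.lr_patience
        if reduce_lr:
            self.since_lr = 0
        return {"reduce_lr": reduce_lr, "stop": self.since_best >= self.patience}


def pretrain_server(model, dt_i: Dataset, dv: Dataset, epochs: int = 50,
                    seed: int = 0, patience: int = 10, lr_patience: int = 5,
                    lr_factor: float = 0.5):
    """Train the round-0 broadcast model on the server's proxy set DT(I).

    Early-stops on DV and restores the best-DV parameters.  With no data
    (or zero epochs) the randomly initialised model is returned unchanged.
    """
    if dt_i is None or dt_i.n == 0:
        warnings.warn("empty server initial set: broadcasting the random initialization",
                      stacklevel=2)
        return model
    if epochs < 1:
        return model
    plateau = _Plateau(patience, lr_patience)
    lr = model.config.lr
    best_params = model.get_params()
    for t in range(epochs):
        model.train_epoch(dt_i, child_rng(seed, 0x5E, t), lr=lr)
        loss = model.val_nrmse(dv) if dv is not None and dv.n else np.inf
        if loss <= plateau.best:
            best_params = model.get_params()
        state = plateau.update(loss)
        if state["reduce_lr"]:
            lr *= lr_factor
        if state["stop"]:
            break
    model.set_params(best_params)
    return model


def fit_centralized(model, train: Dataset, val: Dataset | None, epochs: int,
                    seed: int = 0, patience: int = 10, lr_patience: int = 5,
                    lr_factor: float = 0.5) -> pd.DataFrame:
    """Plain (non-federated) training loop with the same schedule semantics.

    Each epoch is one shuffled pass of mini-batch SGD plus, for DRF
    models, the leaf-update pass.  Returns the per-epoch validation log.
    """
    plateau = _Plateau(patience, lr_patience)
    lr = model.config.lr
    rows = []
    for t in range(epochs):
        model.train_epoch(train, child_rng(seed, _EPOCH_TAG, t), lr=lr)
        if val is not None and val.n:
            loss = model.val_nrmse(val)
            rows.append({"round": t + 1, "client_id": 0, "val_nrmse": loss,
                         "n_samples": train.n, "lr": lr})
            state = plateau.update(loss)
            if state["reduce_lr"]:
                lr *= lr_factor
            if state["stop"]:
                break
    return pd.DataFrame(rows)


def run_federation(global_model, client_datasets: list[Dataset], dv: Dataset,
                   config: FedConfig, seed: int = 0) -> FederationResult:
    """Run the full federated loop; every client participates every round."""
    n = len(client_datasets)
    if n == 0:
        raise ValueError("no clients")
    lr = global_model.config.lr if config.lr is None else config.lr
    server_plateau = _Plateau(config.patience, config.lr_patience)
    client_best = [np.inf] * n
    client_since_best = [0] * n
    client_since_lr = [0] * n
    personal = config.mode == "personalized"
    personal_params: list[dict | None] = [None] * n
    rows = []
    rounds_run = 0
    last_client_params: list[dict] = [global_model.get_params() for _ in range(n)]

    for t in range(config.rounds):
        broadcast = global_model.get_params()
        updates, counts = [], []
        for j in range(n):
            init = dict(broadcast)
            if personal and personal_params[j] is not None:
                init.update(personal_params[j])
            worker = global_model.clone()
            upd = client_update(worker, init, client_datasets[j],
                                child_rng(seed, _EPOCH_TAG, t * n + j), lr)
            updates.append(upd)
            counts.append(upd.n_samples)
            last_client_params[j] = upd.params
            if personal:
                personal_params[j] = {k: v for k, v in upd.params.items()
                                      if k.startswith(PERSONAL_PREFIX)}
            # server-side: score this client's updated model on DV before aggregation
            if dv is not None and dv.n and upd.n_samples > 0:
                worker.set_params(upd.params)
                loss = worker.val_nrmse(dv)
                rows.append({"round": t + 1, "client_id": j, "val_nrmse": loss,
                             "n_samples": upd.n_samples, "lr": lr})
                if loss < client_best[j]:
                    client_best[j] = loss
                    client_since_best[j] = 0
                    client_since_lr[j] = 0
                else:
                    client_since_best[j] += 1
                    client_since_lr[j] += 1

        weights = aggregation_weights(counts)
        shared = [{k: v for k, v in upd.params.items()
                   if not (personal and k.startswith(PERSONAL_PREFIX))}
                  for upd in updates]
        floor = getattr(global_model.config, "variance_floor", 1e-4)
        aggregated = federated_average(shared, weights, variance_floor=floor)
        if personal:
            # the global copy of the head stays at its previous value
            aggregated.update({k: v for k, v in broadcast.items()
                               if k.startswith(PERSONAL_PREFIX)})
        global_model.set_params(aggregated)
        rounds_run = t + 1

        if dv is not None and dv.n:
            if personal:
                mean_since_best = float(np.mean(client_since_best))
                if float(np.mean(client_since_lr)) >= config.lr_patience:
                    lr *= config.lr_factor
                    client_since_lr = [0] * n
                if mean_since_best >= config.patience:
                    break
            else:
                state = server_plateau.update(global_model.val_nrmse(dv))
                if state["reduce_lr"]:
                    lr *= config.lr_factor
                if state["stop"]:
                    break

    log = pd.DataFrame(rows, columns=["round", "client_id", "val_nrmse", "n_samples", "lr"])
    return FederationResult(model=global_model, log=log, rounds_run=rounds_run,
                            client_params=last_client_params)
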