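"""Deep Regression Forest head: soft-routed binary trees with Gaussian leaves.

A regression forest of T fixed-topology full binary trees of depth d.
Each tree has 2^(d-1)-1 internal nodes and 2^(d-1) leaves; a neural
network emits one output per internal node (T·(2^(d-1)-1) in total,
sliced contiguously per tree, breadth-first within a tree), a sigmoid
turns each output into the LEFT-branch probability s of that node, and a
sample reaches leaf ℓ with probability

    P(ℓ|x) = prod over the root-to-leaf path of s_v (left) or 1-s_v (right).

Each leaf carries a Gaussian N(mu_ℓ, sigma_ℓ²) over the scalar target;
the tree prediction is sum_ℓ P(ℓ|x)·mu_ℓ and the forest prediction is the
mean over trees.  Training alternates one backprop pass on the negative
log-likelihood of the per-tree Gaussian mixtures (leaves frozen) with a
closed-form responsibility-weighted update of the leaf parameters
(network frozen) that never increases the training NLL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "TreeTopology",
    "LeafDistribution",
    "routing_probabilities",
    "tree_predict",
    "forest_predict",
    "init_leaves",
    "drf_nll",
    "drf_nll_grad_s",
    "update_leaves",
    "forest_nll",
    "update_forest_leaves",
]

VARIANCE_FLOOR = 1e-4
_S_CLIP = 1e-7  # sigmoid outputs are clipped into (0,1) for the likelihood path


@dataclass(frozen=True)
class TreeTopology:
    """Full binary tree, breadth-first node order, root first."""

    depth: int

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("tree depth must be >= 2")

    @property
    def n_leaves(self) -> int:
        return 2 ** (self.depth - 1)

    @property
    def n_internal(self) -> int:
        return self.n_leaves - 1

    def n_outputs(self, n_trees: int) -> int:
        """Network outputs consumed by a forest of ``n_trees`` such trees."""
        return n_trees * self.n_internal


@dataclass
class LeafDistribution:
    """Per-leaf Gaussian parameters for a forest: arrays of shape (T, L)."""

    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mu.shape != self.var.shape:
            raise ValueError("mu and var shapes differ")
        if (self.var < VARIANCE_FLOOR - 1e-12).any():
            raise ValueError("leaf variance below the variance floor")

    @property
    def n_trees(self) -> int:
        return self.mu.shape[0]

    def copy(self) -> "LeafDistribution":
        return LeafDistribution(self.mu.copy(), self.var.copy())


def init_leaves(topo: TreeTopology, n_trees: int) -> LeafDistribution:
    """Leaves start at N(1, 1): every mean 1, every variance 1."""
    shape = (n_trees, topo.n_leaves)
    return LeafDistribution(np.ones(shape), np.ones(shape))


def routing_probabilities(s, topo: TreeTopology) -> np.ndarray:
    """Per-leaf arrival probabilities from internal-node left probabilities.

    ``s`` is (n_internal,) or (batch, n_internal) with entries in [0,1];
    entry v is the probability of taking the LEFT branch at breadth-first
    node v (children of v are 2v+1 and 2v+2).  Returns probabilities over
    the 2^(d-1) leaves, summing to 1 per sample.
    """
    s = np.asarray(s, dtype=float)
    squeeze = s.ndim == 1
    S = np.atleast_2d(s)
    N = topo.n_internal
    if S.shape[1] != N:
        raise ValueError(f"expected {N} routing entries, got {S.shape[1]}")
    if (S < 0).any() or (S > 1).any():
        raise ValueError("routing probabilities must lie in [0, 1]")
    B = S.shape[0]
    node_prob = np.zeros((B, 2 * N + 1))
    node_prob[:, 0] = 1.0
    for v in range(N):
        node_prob[:, 2 * v + 1] = node_prob[:, v] * S[:, v]
        node_prob[:, 2 * v + 2] = node_prob[:, v] * (1.0 - S[:, v])
    P = node_prob[:, N:]
    return P[0] if squeeze else P


def tree_predict(P, mu) -> np.ndarray | float:
    """Expected leaf mean under the routing distribution: sum_ℓ P(ℓ|x)·mu_ℓ."""
    P = np.asarray(P, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if P.shape[-1] != mu.shape[-1]:
        raise ValueError("leaf-count mismatch between routing and leaves")
    out = P @ mu
    return float(out) if np.ndim(out) == 0 else out


def forest_predict(tree_preds) -> np.ndarray | float:
    """Forest prediction is the arithmetic mean of the tree predictions."""
    arr = np.asarray(tree_preds, dtype=float)
    if arr.shape[0] == 0:
        raise ValueError("empty forest")
    out = arr.mean(axis=0)
    return float(out) if np.ndim(out) == 0 else out


def _log_gauss(y: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """log N(y_i; mu_ℓ, var_ℓ) as a (B, L) matrix."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    return -0.5 * (np.log(2 * np.pi * var) + (y - mu) ** 2 / var)


def drf_nll(y, P, mu, var) -> float:
    """Mean negative log mixture likelihood for one tree.

    -mean_i log sum_ℓ P(ℓ|x_i)·N(y_i; mu_ℓ, var_ℓ), computed via
    log-sum-exp so underflow never yields NaN.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    logg = _log_gauss(y, mu, var)
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -np.inf)
    ll = logsumexp(logP + logg, axis=1)
    return float(-np.mean(ll))


def forest_nll(y, S, topo: TreeTopology, leaves: LeafDistribution) -> float:
    """NLL averaged over trees and batch; S is (B, T·n_internal)."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    N = topo.n_internal
    T = leaves.n_trees
    if S.shape[1] != T * N:
        raise ValueError(f"expected {T * N} routing outputs, got {S.shape[1]}")
    total = 0.0
    for t in range(T):
        P = routing_probabilities(S[:, t * N : (t + 1) * N], topo)
        total += drf_nll(y, P, leaves.mu[t], leaves.var[t])
    return total / T


def drf_nll_grad_s(y, S, topo: TreeTopology, leaves: LeafDistribution):
    """Loss and gradient of the forest NLL w.r.t. the sigmoid outputs S.

    The gradient uses the subtree recursion T_v = s_v·T_left + (1-s_v)·T_right
    (T_leaf = scaled leaf density), giving dM/ds_v = pi_v·(T_left - T_right)
    with pi_v the arrival probability of node v — no divisions, stable at
    saturated routing.  S is clipped into (0,1) before use.
    """
    squeeze = np.asarray(S).ndim == 1
    S = np.atleast_2d(np.asarray(S, dtype=float))
    Sc = np.clip(S, _S_CLIP, 1.0 - _S_CLIP)
    B = Sc.shape[0]
    N = topo.n_internal
    T = leaves.n_trees
    L = topo.n_leaves
    grad = np.zeros_like(Sc)
    loss = 0.0
    for t in range(T):
        St = Sc[:, t * N : (t + 1) * N]
        logg = _log_gauss(y, leaves.mu[t], leaves.var[t])  # (B, L)
        c = logg.max(axis=1, keepdims=True)
        gtil = np.exp(logg - c)  # scaled densities, max 1 per row
        # downward pass: arrival probabilities of every node
        node_prob = np.zeros((B, 2 * N + 1))
        node_prob[:, 0] = 1.0
        for v in range(N):
            node_prob[:, 2 * v + 1] = node_prob[:, v] * St[:, v]
            node_prob[:, 2 * v + 2] = node_prob[:, v] * (1.0 - St[:, v])
        # upward pass: subtree mixture values
        Tval = np.zeros((B, 2 * N + 1))
        Tval[:, N:] = gtil
        for v in range(N - 1, -1, -1):
            Tval[:, v] = St[:, v] * Tval[:, 2 * v + 1] + (1.0 - St[:, v]) * Tval[:, 2 * v + 2]
        m = Tval[:, 0]  # scaled mixture density, >= P(argmax leaf) > 0 after clip
        loss += float(-np.mean(np.log(m) + c[:, 0]))
        dm = node_prob[:, :N] * (Tval[:, 1 : 2 * N : 2] - Tval[:, 2 : 2 * N + 1 : 2])
        grad[:, t * N : (t + 1) * N] = -(dm / m[:, None]) / (B * T)
    return loss / T, (grad[0] if squeeze else grad)


def update_leaves(P, y, mu, var, n_iter: int = 1, floor: float = VARIANCE_FLOOR):
    """Responsibility-weighted leaf update for one tree (network frozen).

    Each iteration computes posterior responsibilities
    xi_iℓ ∝ P(ℓ|x_i)·N(y_i; mu_ℓ, var_ℓ) (rows normalised) and then the
    weighted mean/variance M-step; the training-batch NLL is
    non-increasing across iterations.  Leaves with total responsibility
    below 1e-12 keep their previous parameters; variances are floored.
    Returns (mu, var).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if P.shape[0] != y.size:
        raise ValueError("batch-size mismatch between routing and targets")
    if P.shape[0] == 0:
        raise ValueError("empty batch")
    mu = np.array(mu, dtype=float, copy=True)
    var = np.array(var, dtype=float, copy=True)
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -np.inf)
    for _ in range(n_iter):
        logxi = logP + _log_gauss(y, mu, var)
        norm = logsumexp(logxi, axis=1, keepdims=True)
        xi = np.exp(logxi - norm)  # row-stochastic
        w = xi.sum(axis=0)
        ok = w > 1e-12
        new_mu = np.where(ok, (xi * y[:, None]).sum(axis=0) / np.where(ok, w, 1.0), mu)
        resid2 = (y[:, None] - new_mu) ** 2
        new_var = np.where(ok, (xi * resid2).sum(axis=0) / np.where(ok, w, 1.0), var)
        mu = new_mu
        var = np.maximum(new_var, floor)
    return mu, var


def update_forest_leaves(
    y, S, topo: TreeTopology, leaves: LeafDistribution, n_iter: int = 3,
    floor: float = VARIANCE_FLOOR,
) -> LeafDistribution:
    """Apply ``update_leaves`` to every tree of the forest from routing outputs S."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    N = topo.n_internal
    new = leaves.copy()
    for t in range(leaves.n_trees):
        P = routing_probabilities(S[:, t * N : (t + 1) * N], topo)
        new.mu[t], new.var[t] = update_leaves(P, y, leaves.mu[t], leaves.var[t],
                                              n_iter=n_iter, floor=floor)
    return new
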