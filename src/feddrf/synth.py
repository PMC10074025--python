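"""Synthetic drug-response study generator and federated partition protocols.

Emulates the shape of a cell-line drug-screening panel: a cell feature
matrix (transcriptomic-descriptor-like, block-correlated), a drug
feature matrix (chemical-descriptor-like), and one scalar response per
(cell, drug) pair built from a smooth nonlinear surface plus a per-drug
cluster offset and Gaussian noise.  The block-correlation structure
gives the feature-to-image mapping genuine neighbourhoods to find, and
the drug-cluster offsets create the population heterogeneity the
quasi-random allocation protocol turns into non-IID clients.

Partition protocols:

* ``split_random`` — IID split of the training pool among clients, with
  a small server-held initial set DT(I) plus validation DV and hold-out
  DH disjoint from training;
* ``split_quasi_random`` — each of n clients observes only k of the
  drugs (k=2 with 12 clients and 24 drugs is the fully disjoint case;
  k=n_drugs is full overlap); drugs held by several clients have their
  cell-line samples split evenly;
* ``permute_targets`` — the data-corruption protocol: a fixed fraction
  of a client's response values are permuted among themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticStudy",
    "PartitionSpec",
    "generate_study",
    "split_random",
    "split_quasi_random",
    "permute_targets",
]


@dataclass
class SyntheticStudy:
    """One simulated screening panel; samples are (cell, drug) pairs."""

    cell_features: np.ndarray  # (n_cells, p_cell)
    drug_features: np.ndarray  # (n_drugs, p_drug)
    cell_idx: np.ndarray  # (n_samples,) cell of each sample
    drug_idx: np.ndarray  # (n_samples,) drug of each sample
    y: np.ndarray  # (n_samples,)
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.y.size

    @property
    def drug_labels(self) -> np.ndarray:
        """Drug/group label per sample (used by quasi-random allocation)."""
        return self.drug_idx

    def sample_features(self, idx=None) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample (cell feature rows, drug feature rows)."""
        if idx is None:
            idx = np.arange(self.n_samples)
        idx = np.asarray(idx)
        return self.cell_features[self.cell_idx[idx]], self.drug_features[self.drug_idx[idx]]

    def to_frame(self) -> pd.DataFrame:
        Xc, Xd = self.sample_features()
        df = pd.DataFrame(Xc, columns=[f"cell_{i}" for i in range(Xc.shape[1])])
        for i in range(Xd.shape[1]):
            df[f"drug_{i}"] = Xd[:, i]
        df["drug_id"] = self.drug_idx
        df["response"] = self.y
        return df


@dataclass
class PartitionSpec:
    """Index sets for server/client/evaluation splits of one study.

    ``dt_i`` (server initial set) and the client shares partition the
    training pool DT; DV and DH are disjoint from DT and from each other.
    """

    dt_i: np.ndarray
    client_shares: list[np.ndarray]
    dv: np.ndarray
    dh: np.ndarray
    mode: str
    seed: int
    k: int | None = None

    def __post_init__(self):
        pools = [self.dt_i, self.dv, self.dh, *self.client_shares]
        flat = np.concatenate([np.asarray(p) for p in pools])
        if len(np.unique(flat)) != flat.size:
            raise ValueError("splits are not disjoint")

    @property
    def n_clients(self) -> int:
        return len(self.client_shares)

    @property
    def dt(self) -> np.ndarray:
        return np.sort(np.concatenate([self.dt_i, *self.client_shares]))

    def to_manifest(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "k": self.k,
            "dt_i": self.dt_i.tolist(),
            "dv": self.dv.tolist(),
            "dh": self.dh.tolist(),
            "clients": [c.tolist() for c in self.client_shares],
        }


def _block_features(rng, n, p, n_blocks, within_sd=0.6):
    """Block-correlated features: shared latent per block + feature noise."""
    latent = rng.normal(size=(n, n_blocks))
    block_of = np.arange(p) % n_blocks
    loading = rng.uniform(0.7, 1.3, size=p) * rng.choice([-1.0, 1.0], size=p)
    X = latent[:, block_of] * loading + within_sd * rng.normal(size=(n, p))
    return X, latent


def generate_study(
    n_cells: int = 504,
    n_drugs: int = 24,
    p_cell: int = 64,
    p_drug: int = 25,
    noise_sd: float = 0.3,
    cluster_effect: float = 1.0,
    seed: int = 0,
    n_cell_blocks: int = 6,
    n_drug_blocks: int = 4,
) -> SyntheticStudy:
    """Simulate a drug-response panel over all (cell, drug) pairs.

    The default panel shape (504 cell lines × 24 drugs) mirrors a
    CCLE-like screen.  The response is a smooth nonlinear surface — a
    bilinear cell×drug interaction plus per-arm tanh nonlinearities —
    shifted by a per-drug cluster offset scaled by ``cluster_effect``
    and observed with Gaussian noise of sd ``noise_sd``.  With
    ``noise_sd=0`` and ``cluster_effect=0`` the response is an exact
    deterministic function of the features.
    """
    if min(n_cells, n_drugs, p_cell, p_drug) < 1:
        raise ValueError("all sizes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57D]))
    Xc, _ = _block_features(rng, n_cells, p_cell, n_cell_blocks)
    Xd, _ = _block_features(rng, n_drugs, p_drug, n_drug_blocks)

    # smooth response surface directly on the observable features, so the
    # noiseless offset-free response is an exact function of the inputs
    scale_c, scale_d = np.sqrt(1.5 * p_cell), np.sqrt(1.5 * p_drug)
    A = rng.normal(size=(p_cell, 3)) / scale_c
    Bm = rng.normal(size=(p_drug, 3)) / scale_d
    a = rng.normal(size=p_cell) / scale_c
    b = rng.normal(size=p_drug) / scale_d
    drug_offset = rng.normal(size=n_drugs)

    cell_idx, drug_idx = np.meshgrid(np.arange(n_cells), np.arange(n_drugs), indexing="ij")
    cell_idx, drug_idx = cell_idx.ravel(), drug_idx.ravel()
    u = np.tanh(Xc @ A)[cell_idx]  # (n_samples, 3)
    v = np.tanh(Xd @ Bm)[drug_idx]
    y = (
        1.5 * np.sum(u * v, axis=1)
        + np.tanh(Xc @ a)[cell_idx]
        + np.tanh(Xd @ b)[drug_idx]
        + cluster_effect * drug_offset[drug_idx]
        + noise_sd * rng.normal(size=cell_idx.size)
    )
    return SyntheticStudy(
        cell_features=Xc,
        drug_features=Xd,
        cell_idx=cell_idx,
        drug_idx=drug_idx,
        y=y,
        seed=int(seed),
        params={
            "n_cells": n_cells, "n_drugs": n_drugs, "p_cell": p_cell, "p_drug": p_drug,
            "noise_sd": noise_sd, "cluster_effect": cluster_effect,
        },
    )


def _carve_eval_sets(n, server_frac, val_frac, test_frac, rng):
    if server_frac + val_frac + test_frac > 1.0 + 1e-9:
        raise ValueError("fractions sum to more than 1")
    perm = rng.permutation(n)
    n_val = int(round(val_frac * n))
    n_test = int(round(test_frac * n))
    dv, dh = perm[:n_val], perm[n_val : n_val + n_test]
    dt = perm[n_val + n_test :]
    n_server = int(round(server_frac * n))
    dt_i, dt_rest = dt[:n_server], dt[n_server:]
    return dt_i, dt_rest, dv, dh


def split_random(
    study: SyntheticStudy,
    n_clients: int,
    server_frac: float = 0.05,
    val_frac: float = 0.10,
    test_frac: float = 0.10,
    seed: int = 0,
) -> PartitionSpec:
    """IID split: server keeps DT(I) (default 5%) and DV; clients share the rest."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B1]))
    dt_i, dt_rest, dv, dh = _carve_eval_sets(study.n_samples, server_frac,
                                             val_frac, test_frac, rng)
    if len(dt_rest) < n_clients:
        raise ValueError("a client would receive zero samples")
    shares = [np.sort(s) for s in np.array_split(rng.permutation(dt_rest), n_clients)]
    return PartitionSpec(dt_i=np.sort(dt_i), client_shares=shares, dv=np.sort(dv),
                         dh=np.sort(dh), mode="random", seed=int(seed))


def split_quasi_random(
    study: SyntheticStudy,
    n_clients: int = 12,
    k: int = 2,
    server_frac: float = 0.05,
    val_frac: float = 0.10,
    test_frac: float = 0.10,
    seed: int = 0,
) -> PartitionSpec:
    """Drug-clustered split: each client observes only ``k`` drugs.

    When ``n_clients * k == n_drugs`` the drug sets are a disjoint cover
    (the no-overlap case); for larger ``k`` each client draws a random
    sample of k drugs and drugs held by several clients have their
    cell-line samples split evenly among them.
    """
    n_drugs = int(study.drug_idx.max()) + 1
    if k < 1 or k > n_drugs:
        raise ValueError(f"k must be in [1, {n_drugs}]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B2]))
    dt_i, dt_rest, dv, dh = _carve_eval_sets(study.n_samples, server_frac,
                                             val_frac, test_frac, rng)

    if n_clients * k == n_drugs:
        drugs = rng.permutation(n_drugs)
        drug_sets = [np.sort(drugs[j * k : (j + 1) * k]) for j in range(n_clients)]
    else:
        drug_sets = [np.sort(rng.choice(n_drugs, size=k, replace=False))
                     for _ in range(n_clients)]

    holders: dict[int, list[int]] = {}
    for j, ds in enumerate(drug_sets):
        for d in ds:
            holders.setdefault(int(d), []).append(j)

    shares: list[list[int]] = [[] for _ in range(n_clients)]
    drug_of = study.drug_idx[dt_rest]
    for d, clients in holders.items():
        pool = rng.permutation(dt_rest[drug_of == d])
        for j, chunk in zip(clients, np.array_split(pool, len(clients))):
            shares[j].extend(chunk.tolist())
    share_arrays = [np.sort(np.array(s, dtype=int)) for s in shares]
    if any(s.size == 0 for s in share_arrays):
        raise ValueError("infeasible (k, n_clients) combination: empty client share")
    return PartitionSpec(dt_i=np.sort(dt_i), client_shares=share_arrays, dv=np.sort(dv),
                         dh=np.sort(dh), mode="quasi_random", seed=int(seed), k=int(k))


def permute_targets(y, fraction: float = 0.2, seed: int = 0) -> np.ndarray:
    """Permute a fixed fraction of response values among themselves.

    Exactly ``round(fraction * n)`` positions are selected; their values
    are shuffled in place, so the response multiset is preserved and at
    most that many positions change.  Features are untouched (the caller
    keeps them); returns the corrupted copy of ``y``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    y = np.array(y, dtype=float, copy=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B3]))
    n_swap = int(round(fraction * y.size))
    if n_swap < 2:
        return y
    pos = rng.choice(y.size, size=n_swap, replace=False)
    y[pos] = y[rng.permutation(pos)]
    return y
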