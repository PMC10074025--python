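"""REFINED feature-to-image mapping.

Tabular biomedical features (transcriptomic descriptors, chemical
descriptors) have no natural 2D ordering, so convolution cannot exploit
neighbourhoods in the raw column order.  REFINED assigns each feature to
a pixel of a compact square image such that features that behave
similarly across samples land near each other:

1. compute a pairwise feature distance matrix from the data;
2. embed the features in the plane with metric MDS;
3. snap the embedding onto a discrete grid under the constraint that no
   two features share a cell, then locally refine the assignment by
   strictly stress-decreasing moves (pairwise swaps and relocations to
   free cells).

The map is fitted once, on the data available to the server, and then
broadcast; every party renders samples to images with the same map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

__all__ = [
    "FeatureDistance",
    "RefinedMap",
    "feature_distance_matrix",
    "initial_embedding",
    "assign_pixels",
    "assignment_stress",
    "to_image",
    "from_image",
    "fit_refined_map",
]


@dataclass
class FeatureDistance:
    """Symmetric pairwise distance between feature columns."""

    matrix: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if (m < -1e-12).any():
            raise ValueError("distance matrix must be non-negative")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        self.matrix = m

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RefinedMap:
    """Bijective assignment of feature indices to cells of a g×g grid."""

    grid_side: int
    assignment: np.ndarray  # (p, 2) int rows of (row, col)
    stress: float
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        g = self.grid_side
        if a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("assignment must be (p, 2)")
        if a.shape[0] > g * g:
            raise ValueError(f"{a.shape[0]} features exceed grid capacity {g * g}")
        if (a < 0).any() or (a >= g).any():
            raise ValueError("assigned cell outside the grid")
        cells = {tuple(rc) for rc in a.tolist()}
        if len(cells) != a.shape[0]:
            raise ValueError("assignment not injective: two features share a cell")
        self.assignment = a
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(a.shape[0])]

    @property
    def n_features(self) -> int:
        return self.assignment.shape[0]

    def to_json(self) -> str:
        obj = {
            "grid_side": self.grid_side,
            "stress": self.stress,
            "assignment": {
                name: [int(r), int(c)]
                for name, (r, c) in zip(self.feature_names, self.assignment)
            },
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RefinedMap":
        obj = json.loads(text)
        names = list(obj["assignment"])
        assignment = np.array([obj["assignment"][n] for n in names], dtype=int)
        return cls(
            grid_side=int(obj["grid_side"]),
            assignment=assignment,
            stress=float(obj["stress"]),
            feature_names=names,
        )


def feature_distance_matrix(X, feature_names=None, metric: str = "euclidean") -> FeatureDistance:
    """Pairwise distance between feature columns of a samples×features matrix.

    Columns are standardised internally (zero mean, unit variance;
    constant columns map to all-zero).  ``metric`` is ``"euclidean"``
    (Euclidean distance between standardised columns, scaled by 1/sqrt(n)
    so two exactly anti-correlated columns are at distance 2) or
    ``"correlation"`` (1 - |Pearson r|).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D (samples × features)")
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if not np.isfinite(X).all():
        raise ValueError("non-numeric or non-finite entries in X")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if metric == "euclidean":
        D = squareform(pdist(Z.T, metric="euclidean")) / np.sqrt(n)
    elif metric == "correlation":
        with np.errstate(invalid="ignore"):
            C = (Z.T @ Z) / n
        D = 1.0 - np.abs(np.clip(C, -1.0, 1.0))
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return FeatureDistance(matrix=D, feature_names=list(feature_names))


def initial_embedding(d: FeatureDistance, grid_side: int, seed: int = 0) -> np.ndarray:
    """Metric-MDS embedding of the features, rescaled to the grid.

    Returns p×2 coordinates.  The embedding is centred and uniformly
    rescaled (aspect ratio preserved) so its larger extent spans
    [0, grid_side-1]; deterministic for a fixed seed.
    """
    D = d.matrix
    p = D.shape[0]
    g = grid_side
    center = (g - 1) / 2.0
    if np.allclose(D, 0.0):
        warnings.warn("degenerate all-zero distance matrix: placing all features at grid center",
                      stacklevel=2)
        return np.full((p, 2), center)

    # classical (Torgerson) scaling gives a deterministic, near-exact
    # initialisation; SMACOF then polishes the Kruskal stress
    mds = MDS(
        n_components=2,
        metric="precomputed",
        metric_mds=True,
        n_init=1,
        init="classical_mds",
        max_iter=1000,
        eps=1e-12,
        random_state=seed,
        normalized_stress=False,
    )
    coords = mds.fit_transform(D)
    # align to principal axes with fixed sign so output is reproducible
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    for i in range(vt.shape[0]):
        if vt[i, np.argmax(np.abs(vt[i]))] < 0:
            vt[i] = -vt[i]
    coords = coords @ vt.T
    extent = np.ptp(coords, axis=0).max()
    if extent > 0:
        coords = coords * (g - 1) / extent
    return coords + center


def _grid_cells(g: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)  # lexicographic (row, col)


def assignment_stress(coords: np.ndarray, assignment: np.ndarray) -> float:
    """Sum of squared discrepancies between embedding and grid distances."""
    d_target = pdist(coords)
    d_grid = pdist(assignment.astype(float))
    return float(np.sum((d_target - d_grid) ** 2))


def assign_pixels(
    coords: np.ndarray,
    grid_side: int,
    max_iters: int = 50,
    seed: int = 0,
    feature_names=None,
) -> RefinedMap:
    """Snap embedded features to distinct grid cells and refine by hill climbing.

    Greedy initial assignment: features taken in a deterministic order
    (distance from the embedding centroid; several such orders are tried
    and the best final result kept) each snap to their nearest free cell,
    ties broken by lowest (row, col).  Refinement repeatedly sweeps over
    all feature pairs (swap) and feature/free-cell pairs (relocate),
    accepting only moves that strictly decrease the total stress
    sum_{i<j} (d_ij - grid_dist_ij)^2 where d is the embedding distance.
    Each climb stops after ``max_iters`` sweeps or a sweep with no
    accepted move.  ``seed`` drives the extra random restarts used on
    small instances; everything else is deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    p = coords.shape[0]
    g = grid_side
    if p > g * g:
        raise ValueError(f"cannot place {p} features on a {g}×{g} grid")

    cells = _grid_cells(g)
    centroid = coords.mean(axis=0)
    dist_c = np.linalg.norm(coords - centroid, axis=1)
    orders = [
        sorted(range(p), key=lambda i: (-dist_c[i], i)),  # farthest first
        sorted(range(p), key=lambda i: (dist_c[i], i)),  # nearest first
        list(range(p)),
    ]
    D = squareform(pdist(coords))
    starts = []
    for order in orders:
        free = np.ones(len(cells), dtype=bool)
        assignment = np.zeros((p, 2), dtype=int)
        for i in order:
            d2 = np.sum((cells - coords[i]) ** 2, axis=1)
            d2[~free] = np.inf
            # argmin on lexicographic cells => lowest (row, col) tie-break
            j = int(np.argmin(d2))
            assignment[i] = cells[j]
            free[j] = False
        starts.append(assignment)
    # jointly optimal snap (minimum total squared displacement)
    cost = np.sum((coords[:, None, :] - cells[None, :, :]) ** 2, axis=2)
    rows, cols = linear_sum_assignment(cost)
    starts.append(cells[cols[np.argsort(rows)]])
    if p <= 24:
        # tiny instances: a few seeded random restarts to hop basins
        restart_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E]))
        for _ in range(6):
            starts.append(cells[restart_rng.choice(len(cells), size=p, replace=False)])

    best_assignment, best_stress = None, np.inf
    for start in starts:
        assignment, stress = _hill_climb(D, start, g, max_iters)
        if stress < best_stress:
            best_assignment, best_stress = assignment, stress
    # deterministic basin hopping: kick the worst-fitting pairs and re-climb
    for kick in range(4):
        A = best_assignment.copy()
        gd = pdist(A.astype(float))
        contrib = (squareform(D, checks=False) - gd) ** 2
        order = np.argsort(contrib)[::-1]
        if kick >= len(order):
            break
        i, j = _pair_from_condensed(int(order[kick]), p)
        A[[i, j]] = A[[j, i]]
        A, stress = _hill_climb(D, A, g, max_iters)
        if stress < best_stress:
            best_assignment, best_stress = A, stress
    names = list(feature_names) if feature_names is not None else None
    return RefinedMap(grid_side=g, assignment=best_assignment, stress=best_stress,
                      feature_names=names or [])


def _pair_from_condensed(idx: int, p: int) -> tuple[int, int]:
    """Row/col of entry ``idx`` of a condensed (upper-triangle) distance vector."""
    i = 0
    while idx >= p - i - 1:
        idx -= p - i - 1
        i += 1
    return i, i + 1 + idx


def _pair_stress(D: np.ndarray, A: np.ndarray, i: int) -> float:
    """Stress terms involving feature i under assignment A."""
    diffs = A - A[i]
    gd = np.sqrt(np.sum(diffs * diffs, axis=1))
    terms = (D[i] - gd) ** 2
    terms[i] = 0.0
    return float(terms.sum())


def _hill_climb(D, assignment, g, max_iters):
    A = assignment.astype(float).copy()
    p = A.shape[0]
    occupied = {tuple(map(int, rc)) for rc in A}
    free_cells = [tuple(c) for c in _grid_cells(g).tolist() if tuple(c) not in occupied]

    pdist_target = squareform(D, checks=False)
    stress = float(np.sum((pdist_target - pdist(A)) ** 2))

    for _ in range(max_iters):
        accepted = 0
        # pairwise swaps
        for i in range(p):
            for j in range(i + 1, p):
                before = _pair_stress(D, A, i) + _pair_stress(D, A, j) \
                    - (D[i, j] - np.linalg.norm(A[i] - A[j])) ** 2
                A[[i, j]] = A[[j, i]]
                after = _pair_stress(D, A, i) + _pair_stress(D, A, j) \
                    - (D[i, j] - np.linalg.norm(A[i] - A[j])) ** 2
                if after < before - 1e-12:
                    stress += after - before
                    accepted += 1
                else:
                    A[[i, j]] = A[[j, i]]
        # relocations to free cells
        if free_cells:
            for i in range(p):
                before = _pair_stress(D, A, i)
                old = A[i].copy()
                best_gain, best_cell = 0.0, None
                for cell in free_cells:
                    A[i] = cell
                    after = _pair_stress(D, A, i)
                    gain = before - after
                    if gain > best_gain + 1e-12:
                        best_gain, best_cell = gain, cell
                A[i] = old
                if best_cell is not None:
                    free_cells.remove(best_cell)
                    free_cells.append((int(old[0]), int(old[1])))
                    A[i] = best_cell
                    stress -= best_gain
                    accepted += 1
        if accepted == 0:
            # escape ladder: chained relocation, then (small p) 3-cycles
            if free_cells and _chained_relocation(D, A, free_cells):
                continue
            if p <= 24 and _three_cycle(D, A):
                continue
            break
    final = float(np.sum((pdist_target - pdist(A)) ** 2))
    return A.astype(int), final


def _three_cycle(D, A) -> bool:
    """First strictly improving cyclic rotation of three features' cells."""
    p = A.shape[0]
    for i in range(p):
        for j in range(p):
            if j == i:
                continue
            for k in range(p):
                if k == i or k == j:
                    continue
                idx = [i, j, k]
                before = _triple_stress(D, A, idx)
                old = A[idx].copy()
                A[idx] = old[[1, 2, 0]]  # i<-j, j<-k, k<-i
                after = _triple_stress(D, A, idx)
                if after < before - 1e-12:
                    return True
                A[idx] = old
    return False


def _triple_stress(D, A, idx) -> float:
    total = 0.0
    for t, i in enumerate(idx):
        total += _pair_stress(D, A, i)
    # pairs within the triple were counted twice
    for a in range(3):
        for b in range(a + 1, 3):
            i, j = idx[a], idx[b]
            total -= (D[i, j] - np.linalg.norm(A[i] - A[j])) ** 2
    return total


def _chained_relocation(D, A, free_cells) -> bool:
    """First strictly improving (i -> free cell, j -> i's old cell) move."""
    p = A.shape[0]
    for i in range(p):
        old_i = A[i].copy()
        for ci, cell in enumerate(free_cells):
            for j in range(p):
                if j == i:
                    continue
                old_j = A[j].copy()
                cross = (D[i, j] - np.linalg.norm(A[i] - A[j])) ** 2
                before = _pair_stress(D, A, i) + _pair_stress(D, A, j) - cross
                A[i], A[j] = cell, old_i
                cross = (D[i, j] - np.linalg.norm(A[i] - A[j])) ** 2
                after = _pair_stress(D, A, i) + _pair_stress(D, A, j) - cross
                if after < before - 1e-12:
                    free_cells[ci] = (int(old_j[0]), int(old_j[1]))
                    return True
                A[i], A[j] = old_i, old_j
    return False


def to_image(x, refined_map: RefinedMap) -> np.ndarray:
    """Render a length-p feature vector as a g×g image; unassigned cells are 0."""
    x = np.asarray(x, dtype=float)
    p = refined_map.n_features
    if x.shape[-1] != p:
        raise ValueError(f"expected {p} features, got {x.shape[-1]}")
    g = refined_map.grid_side
    rows, cols = refined_map.assignment[:, 0], refined_map.assignment[:, 1]
    if x.ndim == 1:
        img = np.zeros((g, g))
        img[rows, cols] = x
        return img
    img = np.zeros(x.shape[:-1] + (g, g))
    img[..., rows, cols] = x
    return img


def from_image(img: np.ndarray, refined_map: RefinedMap) -> np.ndarray:
    """Read the feature vector back out of an image (inverse of ``to_image``)."""
    rows, cols = refined_map.assignment[:, 0], refined_map.assignment[:, 1]
    return np.asarray(img)[..., rows, cols]


def fit_refined_map(
    X,
    grid_side: int | None = None,
    seed: int = 0,
    metric: str = "euclidean",
    max_iters: int = 50,
    feature_names=None,
) -> RefinedMap:
    """Fit the full pipeline: distances -> MDS -> constrained grid assignment.

    ``grid_side`` defaults to ceil(sqrt(p)), the smallest square that can
    hold one feature per pixel.
    """
    d = feature_distance_matrix(X, feature_names=feature_names, metric=metric)
    p = d.n_features
    if grid_side is None:
        grid_side = int(np.ceil(np.sqrt(p)))
    coords = initial_embedding(d, grid_side, seed=seed)
    return assign_pixels(coords, grid_side, max_iters=max_iters, seed=seed,
                         feature_names=d.feature_names)
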