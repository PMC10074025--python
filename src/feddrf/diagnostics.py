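"""Client-heterogeneity diagnostic from validation-loss trajectories.

In a cross-silo federation the server scores every client's locally
updated model on its own validation set DV each round, giving one loss
trajectory per client.  If clients sample a homogeneous population these
trajectories mix; if each client observes its own sub-population (for
instance, a disjoint set of drugs) the trajectories separate.  The
diagnostic is a Gelman–Rubin-style ratio built from the between- and
within-trajectory variances of the logged losses.

With n clients observed for m-1 rounds up to convergence point m:

    B   = (m-1)/(n-1) * sum_j (xbar_j - xbar)^2      between-trajectory
    W_j = 1/(m-2)     * sum_t (x_t^(j) - xbar_j)^2   within-trajectory
    W   = mean_j W_j
    R   = (alpha*B + (1-alpha)*W) / W,   alpha = 1/(m-1)

R stays near 1 when trajectories mix (B -> 0, m moderately large) and
grows well above 1 when clients see distinct population clusters.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryDiagnostics",
    "trajectory_stats",
    "r_statistic",
    "detect_heterogeneity",
    "diagnose_round_log",
    "plot_trajectories",
]


@dataclass
class TrajectoryDiagnostics:
    """Between/within variance decomposition of client loss trajectories."""

    trajectories: np.ndarray  # (n_clients, m-1)
    m: int
    client_means: np.ndarray = field(init=False)
    grand_mean: float = field(init=False)
    between_var: float = field(init=False)
    within_vars: np.ndarray = field(init=False)
    within_var: float = field(init=False)
    alpha: float = field(init=False)

    def __post_init__(self):
        x = np.asarray(self.trajectories, dtype=float)
        n, length = x.shape
        if n < 2:
            raise ValueError("need at least 2 client trajectories")
        if self.m < 3:
            raise ValueError("m must be >= 3 (within-variance divides by m-2)")
        if length != self.m - 1:
            raise ValueError(f"trajectories must have length m-1={self.m - 1}, got {length}")
        self.trajectories = x
        self.client_means = x.mean(axis=1)
        self.grand_mean = float(self.client_means.mean())
        self.between_var = float(
            (self.m - 1) / (n - 1) * np.sum((self.client_means - self.grand_mean) ** 2)
        )
        self.within_vars = np.sum((x - self.client_means[:, None]) ** 2, axis=1) / (self.m - 2)
        self.within_var = float(self.within_vars.mean())
        self.alpha = 1.0 / (self.m - 1)

    @property
    def n_clients(self) -> int:
        return self.trajectories.shape[0]

    def to_dict(self) -> dict:
        r = r_statistic(self)
        return {
            "B": self.between_var,
            "W": self.within_var,
            "alpha": self.alpha,
            "m": self.m,
            "n": self.n_clients,
            "R": r,
        }


def trajectory_stats(trajectories, m: int | None = None) -> TrajectoryDiagnostics:
    """Build the variance decomposition from per-client loss trajectories.

    ``trajectories`` is a sequence of per-client loss sequences.  Ragged
    inputs are truncated to the shortest with a warning.  ``m`` is the
    convergence point; by default it is inferred as (common length + 1),
    i.e. the whole observed trajectory is used.
    """
    seqs = [np.asarray(t, dtype=float).ravel() for t in trajectories]
    if len(seqs) < 2:
        raise ValueError("need at least 2 clients")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        warnings.warn("ragged trajectories: truncating to shortest", stacklevel=2)
    length = min(lengths)
    if m is None:
        m = length + 1
    if m < 3:
        raise ValueError("m must be >= 3")
    if length < m - 1:
        raise ValueError(f"trajectories shorter than m-1={m - 1}")
    x = np.stack([s[: m - 1] for s in seqs])
    return TrajectoryDiagnostics(trajectories=x, m=m)


def r_statistic(diag: TrajectoryDiagnostics) -> float:
    """Mixing diagnostic R = (alpha*B + (1-alpha)*W) / W with alpha=1/(m-1)."""
    b, w, a = diag.between_var, diag.within_var, diag.alpha
    if w <= 0.0:
        if b <= 0.0:
            # fully degenerate: no variation anywhere; trajectories mix trivially
            return 1.0 - a
        warnings.warn("zero within-trajectory variance with B>0: R is infinite", stacklevel=2)
        return math.inf
    return float((a * b + (1.0 - a) * w) / w)


def detect_heterogeneity(r: float, threshold: float = 1.5) -> bool:
    """Flag client-population heterogeneity when R exceeds the threshold.

    The threshold is a tool default; R near 1 indicates well-mixed
    (homogeneous) clients, R >> 1 indicates clustered sub-populations.
    """
    if math.isnan(r):
        raise ValueError("R is NaN")
    return bool(r > threshold)


def diagnose_round_log(
    log: pd.DataFrame, m: int | None = None, threshold: float = 1.5
) -> dict:
    """Run the diagnostic on a federation round log.

    Expects the fed-core log schema with columns (round, client_id,
    val_nrmse).  Returns the JSON-ready report {B, W, alpha, m, n, R, flag}.
    """
    wide = log.pivot_table(index="client_id", columns="round", values="val_nrmse")
    diag = trajectory_stats(wide.to_numpy(), m=m)
    report = diag.to_dict()
    report["flag"] = detect_heterogeneity(report["R"], threshold)
    report["threshold"] = threshold
    return report


def plot_trajectories(log: pd.DataFrame, path: str, title: str = "") -> None:
    """Write a per-client validation-loss trajectory plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cid, grp in log.groupby("client_id"):
        grp = grp.sort_values("round")
        ax.plot(grp["round"], grp["val_nrmse"], alpha=0.7, label=f"client {cid}")
    ax.set_xlabel("round")
    ax.set_ylabel("validation NRMSE")
    if title:
        ax.set_title(title)
    if log["client_id"].nunique() <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
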