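"""Regression evaluation metrics: NRMSE and Pearson correlation.

NRMSE is the root-mean-squared error of the predictions normalised by the
RMSE of the constant mean predictor evaluated on the *same* set:

    NRMSE = sqrt(sum (y - yhat)^2) / sqrt(sum (y - ybar)^2)

so a model that always predicts the evaluation-set mean scores exactly 1,
a perfect model scores 0, and values above 1 are worse than the mean
predictor.  The normalising mean is recomputed on each evaluation set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["nrmse", "pcc", "replicate_summary"]


def _as_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("non-finite entries in targets or predictions")
    return y, yhat


def nrmse(y, yhat) -> float:
    """Normalised RMSE relative to the mean predictor of ``y`` itself."""
    y, yhat = _as_pair(y, yhat)
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom <= 0.0:
        raise ValueError("constant target vector: NRMSE denominator is zero")
    num = float(np.sum((y - yhat) ** 2))
    return float(np.sqrt(num / denom))


def pcc(y, yhat) -> float:
    """Pearson product-moment correlation between targets and predictions."""
    y, yhat = _as_pair(y, yhat)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("constant vector: Pearson correlation undefined")
    return float(stats.pearsonr(y, yhat).statistic)


def replicate_summary(rows: list[dict]) -> pd.DataFrame:
    """Average metric rows over replicate data partitions.

    ``rows`` carry at least (model, replicate, nrmse, pcc); any other
    columns except ``replicate`` are treated as grouping keys.
    """
    df = pd.DataFrame(rows)
    keys = [c for c in df.columns if c not in ("replicate", "nrmse", "pcc")]
    out = df.groupby(keys, as_index=False)[["nrmse", "pcc"]].mean()
    out["n_replicates"] = df.groupby(keys).size().values
    return out
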