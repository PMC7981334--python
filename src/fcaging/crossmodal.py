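"""Cross-modal association of aging effects: FC vs D1 BP vs GMD.

Edge-level FC aging effects are aggregated to nodes ("average nodal
beta": the mean of beta over all connections containing the node),
ROIs are assigned to anatomical regions or functional networks by
argmax over user-supplied probability/score tables, and nodal aging
effects across modalities are related by Pearson correlation and a
joint OLS regression on standardized variables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "average_nodal_beta",
    "average_nodal_beta_table",
    "assign_partition",
    "nodal_correlation",
    "joint_regression",
    "arrange_by_partition",
]


def average_nodal_beta(
    edge_fits: pd.DataFrame, node: int, which: str = "beta_mu"
) -> float:
    """Mean of an edge aging-effect parameter over edges incident to ``node``.

    ``edge_fits`` needs columns node_i, node_j and the parameter column.
    """
    mask = (edge_fits["node_i"] == node) | (edge_fits["node_j"] == node)
    if not mask.any():
        raise ValueError(f"node {node} has no incident edges")
    return float(edge_fits.loc[mask, which].mean())


def average_nodal_beta_table(edge_fits: pd.DataFrame, nodes: list[int]) -> pd.DataFrame:
    """Average nodal beta_mu and beta_sigma for every node, vectorized."""
    out = []
    i = edge_fits["node_i"].to_numpy()
    j = edge_fits["node_j"].to_numpy()
    bm = edge_fits["beta_mu"].to_numpy()
    bs = edge_fits["beta_sigma"].to_numpy()
    for node in nodes:
        mask = (i == node) | (j == node)
        if not mask.any():
            raise ValueError(f"node {node} has no incident edges")
        out.append(
            {
                "node": node,
                "avg_nodal_beta_mu": float(bm[mask].mean()),
                "avg_nodal_beta_sigma": float(bs[mask].mean()),
                "degree": int(mask.sum()),
            }
        )
    return pd.DataFrame(out)


def assign_partition(
    partition: pd.DataFrame, mode: str = "region", size_column: str = "size"
) -> pd.Series:
    """Argmax label per ROI from a probability/score table.

    ``partition`` is indexed by ROI with one column per candidate label
    (plus, for network mode, a ROI-size column).  Region mode assigns
    the label with the highest probability; network mode first scores
    each label as mean map value x ROI size.  Ties go to the first
    (lowest-index) label column, with a warning.
    """
    if mode not in ("region", "network"):
        raise ValueError("mode must be 'region' or 'network'")
    cols = [c for c in partition.columns if c != size_column]
    if not cols:
        raise ValueError("partition table has no label columns")
    scores = partition[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("partition scores must be finite")
    if mode == "network":
        if size_column not in partition.columns:
            raise ValueError(f"network mode needs a {size_column!r} column")
        scores = scores * partition[size_column].to_numpy(dtype=float)[:, None]
    if np.any(scores.max(axis=1) == 0):
        warnings.warn("ROI(s) with all-zero scores; argmax defaults to the first label")
    best = scores.argmax(axis=1)  # argmax returns the first max: documented tie rule
    ties = (scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} ROI(s) had tied scores; first label used")
    return pd.Series([cols[b] for b in best], index=partition.index, name=mode)


def nodal_correlation(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    exclude: list | None = None,
) -> tuple[float, float]:
    """Pearson r and two-sided p between two per-ROI aging-effect series.

    Series are aligned on their shared index; ROIs in ``exclude`` are
    dropped first (sensitivity analysis for high-leverage regions).
    """
    x = pd.Series(x) if not isinstance(x, pd.Series) else x
    y = pd.Series(y) if not isinstance(y, pd.Series) else y
    shared = x.index.intersection(y.index)
    if exclude:
        shared = shared.difference(pd.Index(exclude))
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared ROIs after exclusion, got {len(shared)}")
    xv = x.loc[shared].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("constant input series")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def joint_regression(
    response: pd.Series,
    predictors: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of the response on all predictors, raw and standardized.

    Variables are aligned on the shared ROI index and z-scored for the
    standardized fit (population SD).  Returns one row per predictor
    with raw and standardized coefficients, two-sided p values, and the
    model R-squared; an ``_intercept`` row carries the raw intercept.
    """
    shared = response.index.intersection(predictors.index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 complete ROIs, got {len(shared)}")
    yv = response.loc[shared].to_numpy(dtype=float)
    xv = predictors.loc[shared].to_numpy(dtype=float)
    corr = np.corrcoef(xv, rowvar=False)
    if xv.shape[1] > 1 and np.any(np.abs(corr[~np.eye(xv.shape[1], dtype=bool)]) > 0.999):
        raise ValueError("collinear predictors (|r| > 0.999)")

    raw = sm.OLS(yv, sm.add_constant(xv)).fit()
    z = lambda a: (a - a.mean(axis=0)) / a.std(axis=0)
    std = sm.OLS(z(yv), sm.add_constant(z(xv))).fit()

    rows = [
        {
            "predictor": "_intercept",
            "coef_raw": float(raw.params[0]),
            "coef_std": float(std.params[0]),
            "p": float(raw.pvalues[0]),
            "r_squared": float(raw.rsquared),
        }
    ]
    for k, name in enumerate(predictors.columns, start=1):
        rows.append(
            {
                "predictor": name,
                "coef_raw": float(raw.params[k]),
                "coef_std": float(std.params[k]),
                "p": float(std.pvalues[k]),
                "r_squared": float(raw.rsquared),
            }
        )
    return pd.DataFrame(rows)


def arrange_by_partition(
    matrix: np.ndarray, labels: list
) -> tuple[np.ndarray, np.ndarray, list]:
    """Reorder a symmetric edge matrix into contiguous partition blocks.

    Returns (reordered matrix, permutation, block boundary indices as a
    list of (label, start, stop)).  Content is unchanged: the output is
    matrix[perm][:, perm].
    """
    labels = list(labels)
    n = len(labels)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (n, n):
        raise ValueError("labels must cover all nodes")
    order = np.argsort(np.asarray(labels, dtype=object), kind="stable")
    arranged = matrix[np.ix_(order, order)]
    bounds = []
    sorted_labels = [labels[k] for k in order]
    start = 0
    for k in range(1, n + 1):
        if k == n or sorted_labels[k] != sorted_labels[start]:
            bounds.append((sorted_labels[start], start, k))
            start = k
    return arranged, order, bounds
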