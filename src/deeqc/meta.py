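"""Meta-analysis over expression matrices and differential-expression tables.

Three building blocks: pairwise correlation matrices across runs (or,
transposed, across genes), complete-linkage hierarchical clustering with
flat clusters formed by cutting at a fraction of the maximum merge height,
and a signed rank statistic for comparing differential-expression results
between sources (sign of fold change times -log2 p-value, compared by
Spearman correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .expression import ExpressionMatrix


@dataclass
class CorrelationMatrix:
    matrix: pd.DataFrame  # symmetric, labels x labels
    method: str  # "spearman" or "pearson"
    warnings: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.matrix.index)


@dataclass
class ClusterAssignment:
    assignment: pd.Series  # label -> cluster id (1-based)
    cut_fraction: float
    cut_height: float
    merge_heights: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.nunique())


def correlation_matrix(
    m: ExpressionMatrix, axis: str = "runs", method: str = "spearman"
) -> CorrelationMatrix:
    """Pairwise correlations between runs (columns) or genes (rows).

    ``axis="genes"`` transposes first, so items are features correlated
    over runs.  Constant vectors yield NA rows/columns plus a warning
    record rather than an error.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if axis not in ("runs", "genes"):
        raise ValueError(f"axis must be 'runs' or 'genes', got {axis!r}")
    data = m.values if axis == "runs" else m.values.T  # items as columns
    if data.shape[1] < 2:
        raise ValueError("need at least 2 items to correlate")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations per item")
    warns = []
    for label in data.columns[data.std(axis=0) == 0]:
        warns.append(f"constant vector: {label}; correlations set to NA")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pandas warns on constant columns
        corr = data.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return CorrelationMatrix(corr, method, warns)


def cluster_cut(
    cm: CorrelationMatrix, cut_fraction: float, linkage: str = "complete"
) -> ClusterAssignment:
    """Complete-linkage clustering of 1 - r distances, cut at a height fraction.

    Flat clusters are formed at ``cut_fraction`` times the maximum merge
    height of the dendrogram.  NA correlations (constant vectors) are
    treated as zero correlation before the distance transform.
    """
    if not 0.0 < cut_fraction <= 1.0:
        raise ValueError("cut_fraction must be in (0, 1]")
    labels = cm.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    corr = cm.matrix.fillna(0.0).to_numpy(dtype=float)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    max_height = Z[:, 2].max() if len(Z) else 0.0
    cut_height = cut_fraction * max_height
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    assignment = pd.Series(flat, index=labels, name="cluster")
    return ClusterAssignment(assignment, cut_fraction, cut_height, Z[:, 2].copy())


def de_rank_statistic(table: pd.DataFrame, fc_col: str = "fc", p_col: str = "p") -> pd.Series:
    """Signed significance score: sign(fold change) * -log2(p-value).

    A p-value of 1 scores 0 regardless of direction; zero fold changes
    carry sign 0.  p-values must lie in (0, 1].
    """
    p = table[p_col].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        bad = table.index[(p <= 0) | (p > 1)].tolist()
        raise ValueError(f"p-values outside (0, 1] for: {bad[:5]}")
    score = np.sign(table[fc_col].to_numpy(dtype=float)) * (-np.log2(p))
    return pd.Series(score, index=table.index, name="signed_score")


def de_concordance(a: pd.DataFrame, b: pd.DataFrame,
                   fc_col: str = "fc", p_col: str = "p") -> float:
    """Spearman correlation of signed significance scores on shared genes."""
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} shared genes; need >= 3")
    sa = de_rank_statistic(a.loc[common], fc_col, p_col)
    sb = de_rank_statistic(b.loc[common], fc_col, p_col)
    rho, _ = spearmanr(sa, sb)
    return float(rho)
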