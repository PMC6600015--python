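"""Unsupervised structure analysis: hierarchical clustering, PCA, and
two-cluster drug-response tests.

Clustering is complete-linkage over the Euclidean metric (so merge heights
are monotone), the two-cluster cut is taken below the final merge, and
cluster-wise drug response differences use Welch's t test with
Benjamini–Hochberg adjustment across drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .evaluation import bh_adjust, welch_group_test

__all__ = [
    "Dendrogram",
    "hierarchical_cluster",
    "cut_two_clusters",
    "pca",
    "cluster_drug_response_test",
]


@dataclass
class Dendrogram:
    """Agglomerative merge sequence with labels.

    ``linkage`` is the scipy (n−1) × 4 matrix; complete linkage guarantees
    non-decreasing heights along the merge sequence.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Export the tree as a Newick string with merge heights as branch
        lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return _fmt(tree, tree.dist) + ";"


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Complete-linkage clustering over a Euclidean metric.

    ``axis='rows'`` clusters cell lines, ``axis='columns'`` clusters
    features/drugs. Rows containing missing values are dropped with a
    warning (complete-case clustering).
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    complete = matrix.dropna(axis=0)
    if len(complete) < len(matrix):
        warnings.warn(
            f"dropping {len(matrix) - len(complete)} row(s) with missing values",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise ValueError("clustering requires at least 2 complete items")
    Z = hierarchy.linkage(complete.to_numpy(dtype=float), method="complete",
                          metric="euclidean")
    return Dendrogram(linkage=Z, labels=list(complete.index))


def cut_two_clusters(dendrogram: Dendrogram) -> pd.Series:
    """Binary labels from cutting just below the final merge."""
    flat = hierarchy.fcluster(dendrogram.linkage, t=2, criterion="maxclust")
    return pd.Series(flat - 1, index=dendrogram.labels, name="cluster")


def pca(
    matrix: pd.DataFrame, n_components: int
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Principal component analysis by SVD of the centered matrix.

    Returns (scores, loadings, variance_fractions); variance fractions are
    non-increasing and scores·loadingsᵀ reconstructs the centered matrix
    when ``n_components`` equals the rank. Component signs are fixed so the
    largest-magnitude loading of each component is positive.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input must not contain missing values")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    k = min(n_components, rank)
    # deterministic sign convention
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = pd.DataFrame(
        U[:, :k] * S[:k], index=matrix.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    loadings = pd.DataFrame(
        Vt[:k].T, index=matrix.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    var_frac = (S**2 / np.sum(S**2))[:k]
    return scores, loadings, var_frac


def cluster_drug_response_test(
    auc: pd.DataFrame, cluster_labels: pd.Series
) -> pd.DataFrame:
    """Welch's t test per drug between two cell-line clusters.

    Drugs where either cluster has fewer than 2 non-missing AUCs are
    skipped (logged in the output as NaN rows are absent). p-values are
    BH-adjusted across the tested drugs.
    """
    labels = cluster_labels.reindex(auc.index)
    rows = []
    for drug in auc.columns:
        vals = auc[drug].dropna()
        lab = labels.loc[vals.index].dropna()
        vals = vals.loc[lab.index]
        uniq = lab.unique()
        if len(uniq) != 2 or min((lab == u).sum() for u in uniq) < 2:
            continue
        if vals.std() == 0:
            rows.append({"drug": drug, "t": 0.0, "df": float(len(vals) - 2), "p": 1.0})
            continue
        t, df, p = welch_group_test(vals.to_numpy(), lab.to_numpy())
        rows.append({"drug": drug, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
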