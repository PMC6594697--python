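"""Mark-mark correlation and hierarchical clustering of the histone code.

Pearson correlation of the binary matrix's columns (the phi coefficient
on binary data) gives an M x M mark association matrix; agglomerative
clustering with complete linkage on distance ``1 - r`` partitions the
marks into k clusters, mirroring the corrplot + hclust analysis that
identified five clusters of histone modifications. Marks with constant
columns have undefined correlations; they are flagged and excluded from
clustering rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ShapeError


@dataclass
class MarkCorrelationMatrix:
    """M x M correlation matrix with an explicit defined-mark mask.

    ``values`` holds NaN for any pair involving a constant (undefined)
    column; ``defined`` marks the columns with positive variance.
    """
    values: pd.DataFrame
    defined: pd.Series

    @property
    def marks(self) -> list[str]:
        return list(self.values.columns)

    @property
    def defined_marks(self) -> list[str]:
        return [m for m in self.marks if self.defined[m]]


@dataclass
class ClusterResult:
    """k-cluster partition of marks plus the merge history.

    ``labels`` maps mark -> cluster in 1..k (relabelled by first
    appearance in column order, so the partition is deterministic);
    ``linkage`` is the SciPy merge matrix; ``leaf_order`` the dendrogram
    leaf sequence used for corrplot-style matrix ordering; ``excluded``
    lists marks dropped for undefined correlations.
    """
    labels: pd.Series
    linkage: np.ndarray
    leaf_order: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


def pearson_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between rows of ``x`` with constant rows
    flagged instead of silently zeroed.

    Returns ``(corr, defined)`` where undefined entries are NaN and the
    diagonal of defined rows is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    sd = x.std(axis=1)
    defined = sd > 0
    centred = x - x.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centred @ centred.T / x.shape[1]
        denom = np.outer(sd, sd)
        corr = cov / denom
    corr = np.clip(corr, -1.0, 1.0)
    corr[~defined, :] = np.nan
    corr[:, ~defined] = np.nan
    d = np.flatnonzero(defined)
    corr[d, d] = 1.0
    return corr, defined


def phi_correlation(matrix: pd.DataFrame) -> MarkCorrelationMatrix:
    """Phi (Pearson-on-binary) correlation between the matrix's mark columns."""
    if len(matrix) < 2:
        raise ShapeError("need at least 2 nucleosome rows to correlate marks")
    corr, defined = pearson_rows(matrix.to_numpy(dtype=float).T)
    cols = list(matrix.columns)
    return MarkCorrelationMatrix(
        values=pd.DataFrame(corr, index=cols, columns=cols),
        defined=pd.Series(defined, index=cols),
    )


def cluster_marks(corr: MarkCorrelationMatrix, k: int,
                  linkage_method: str = "complete") -> ClusterResult:
    """Agglomerative clustering of marks on distance ``1 - r``.

    Undefined-column marks are excluded (reported in ``excluded``);
    ``k`` must satisfy ``1 <= k <=`` number of clustered marks. Cutting
    the merge history at ``k`` yields the labels; ties are broken
    deterministically by SciPy's ordering of the condensed distances.
    """
    included = corr.defined_marks
    excluded = [m for m in corr.marks if m not in included]
    m = len(included)
    if not 1 <= k <= m:
        raise ValueError(f"k={k} outside 1..{m} (clustered marks)")
    r = corr.values.loc[included, included].to_numpy(dtype=float)
    dist = 1.0 - r
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    if m == 1:
        return ClusterResult(labels=pd.Series([1], index=included),
                             linkage=np.zeros((0, 4)), leaf_order=list(included),
                             excluded=excluded)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels.append(relabel[lab])
    leaf_order = [included[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(labels=pd.Series(labels, index=included),
                         linkage=z, leaf_order=leaf_order, excluded=excluded)


def order_marks(result: ClusterResult,
                corr: MarkCorrelationMatrix | None = None) -> list[str]:
    """Corrplot-style ordering: the dendrogram leaf sequence (marks of one
    cluster are contiguous under any cut of the merge history)."""
    return list(result.leaf_order)


def reorder_correlation(corr: MarkCorrelationMatrix,
                        order: list[str]) -> pd.DataFrame:
    """Reindex the correlation matrix by a mark permutation."""
    return corr.values.loc[order, order]


def plot_correlation_heatmap(corr: MarkCorrelationMatrix,
                             result: ClusterResult | None = None,
                             path=None):
    """Heatmap of the (leaf-ordered) correlation matrix, red = negative to
    blue = positive, with black boxes around clusters."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.leaf_order if result is not None else corr.marks
    mat = corr.values.loc[order, order].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(0.4 * len(order) + 2,) * 2)
    im = ax.imshow(mat, cmap="RdBu", vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if result is not None:
        labels = [result.labels[m] for m in order]
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                ax.add_patch(plt.Rectangle(
                    (start - 0.5, start - 0.5), i - start, i - start,
                    fill=False, edgecolor="black", linewidth=1.5))
                start = i
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
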