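"""Covariance-based grouping of regional features.

Regions are clustered by agglomerative hierarchical clustering on the
distance 1 - rho, where rho is the Spearman rank-order correlation between
region columns across participants.  Spearman (rather than Pearson) makes
the grouping invariant to any strictly monotone transform of a feature.
The tree is cut to a requested number of clusters; no automatic cut
criterion is applied.  The same procedure can be re-applied to the members
of one cluster to obtain sub-clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr


@dataclass
class ClusterAssignment:
    labels: pd.Series                    # region -> cluster id (1..k)
    linkage: np.ndarray = field(repr=False)
    n_clusters: int = 0
    method: dict = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_csv(self, path: str | Path) -> None:
        self.labels.rename("cluster").rename_axis("region").to_csv(path)

    def linkage_json(self, path: str | Path | None = None) -> str:
        d = {"linkage": self.linkage.tolist(), "method": self.method,
             "n_clusters": self.n_clusters}
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def spearman_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-order correlation matrix of the feature columns."""
    if len(features) < 3:
        raise ValueError("need at least 3 participants")
    const = [c for c in features.columns if features[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant feature column(s): {const}")
    rho = spearmanr(features.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=features.columns, columns=features.columns)


def hierarchical_clusters(
    corr: pd.DataFrame, k: int, linkage: str = "average"
) -> ClusterAssignment:
    """Cut an agglomerative tree on distance 1 - rho into exactly k clusters.

    Labels are renumbered 1..k in order of first appearance along the
    column order, so the partition (not the numbering) is what is
    determined by the data.
    """
    n = corr.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in 1..{n}")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # contiguous relabeling in order of appearance
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap) + 1
        labels[i] = remap[r]
    return ClusterAssignment(
        labels=pd.Series(labels, index=corr.index, name="cluster"),
        linkage=Z,
        n_clusters=int(labels.max()),
        method={"distance": "1 - spearman rho", "linkage": linkage, "k": k},
    )


def cluster_features(
    features: pd.DataFrame, k: int, linkage: str = "average"
) -> ClusterAssignment:
    """Convenience: Spearman matrix then hierarchical cut."""
    return hierarchical_clusters(spearman_matrix(features), k, linkage=linkage)


def subcluster(
    features: pd.DataFrame,
    parent: ClusterAssignment,
    label: int,
    k: int,
    linkage: str = "average",
) -> ClusterAssignment:
    """Re-run the clustering on the member columns of one parent cluster."""
    members = parent.members(label)
    if len(members) < k:
        raise ValueError(
            f"cluster {label} has {len(members)} members, fewer than k={k}"
        )
    return cluster_features(features[members], k, linkage=linkage)
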