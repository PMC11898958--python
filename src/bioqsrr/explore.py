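"""Exploratory analysis of the chromatographic endpoint table:
correlation matrix, auto-scaled hierarchical clustering and heat-map
export.

Clustering groups compounds by their joint biomolecule-affinity
profile (lipophilicity, phospholipid affinity, albumin binding); with
the default three-group cut the clusters are labelled low / medium /
high bioaccumulation potential by ranking the cluster means of the C18
lipophilicity index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .datatypes import RetentionTable
from .preprocess import autoscale

__all__ = [
    "ClusteringResult",
    "correlation_matrix",
    "hierarchical_cluster",
    "cut_tree",
    "bioaccumulation_groups",
    "heatmap_export",
    "DEFAULT_CLUSTER_COLUMNS",
]

#: the three independent measurements; %HSA is a deterministic transform
#: of logk_hsa and would double-weight albumin binding
DEFAULT_CLUSTER_COLUMNS = ("chi_c18", "chi_iam", "logk_hsa")


@dataclass
class ClusteringResult:
    """Agglomerative merge tree over the compound set."""

    linkage_method: str
    distance: str
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    leaf_order: list[int]
    compound_names: list[str]
    columns: list[str]
    scaled: pd.DataFrame  # auto-scaled data the tree was built on

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def _endpoint_frame(table: RetentionTable, columns) -> pd.DataFrame:
    cols = list(columns)
    data = {c: table.column(c) for c in cols}
    return pd.DataFrame(data, index=table.names)


def correlation_matrix(table: RetentionTable, columns=DEFAULT_CLUSTER_COLUMNS) -> pd.DataFrame:
    """Pearson correlation matrix of the chosen endpoint columns."""
    df = _endpoint_frame(table, columns)
    if len(df) < 3:
        raise ValueError("need at least 3 compounds for a correlation matrix")
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant column(s): {list(sd.index[sd == 0])}")
    return df.corr(method="pearson")


def hierarchical_cluster(
    table: RetentionTable,
    columns=DEFAULT_CLUSTER_COLUMNS,
    linkage: str = "ward",
    distance: str = "euclidean",
) -> ClusteringResult:
    """Agglomerative clustering of compounds on auto-scaled endpoints.

    Auto-scaling is applied internally so each index contributes on an
    equal footing regardless of its native scale.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 compounds to cluster")
    if linkage not in ("ward", "single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    df = _endpoint_frame(table, columns)
    scaled = autoscale(df)
    Z = hierarchy.linkage(scaled.to_numpy(), method=linkage, metric=distance)
    leaves = hierarchy.leaves_list(Z)
    return ClusteringResult(
        linkage_method=linkage,
        distance=distance,
        linkage_matrix=Z,
        leaf_order=[int(i) for i in leaves],
        compound_names=list(df.index),
        columns=list(df.columns),
        scaled=scaled,
    )


def cut_tree(result: ClusteringResult, rule: str = "gap", k: int | None = None) -> pd.Series:
    """Cut the merge tree into flat groups.

    ``rule="k"`` produces exactly ``k`` groups; ``rule="gap"`` cuts at
    the largest gap between successive merge heights.  Returns integer
    labels (1-based, scipy convention) indexed by compound name.
    """
    n = len(result.compound_names)
    if rule == "k":
        if k is None:
            raise ValueError("rule 'k' requires k")
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}]")
        labels = hierarchy.fcluster(result.linkage_matrix, t=k, criterion="maxclust")
    elif rule == "gap":
        heights = result.merge_heights
        if heights.size < 2:
            labels = np.ones(n, dtype=int)
        else:
            gaps = np.diff(heights)
            # cutting just above the merge before the largest gap leaves
            # (n - 1 - index) + 1 clusters
            i = int(np.argmax(gaps))
            k_gap = n - 1 - i
            labels = hierarchy.fcluster(result.linkage_matrix, t=k_gap, criterion="maxclust")
    else:
        raise ValueError(f"unknown cut rule {rule!r}")
    return pd.Series(labels, index=result.compound_names, name="group")


def bioaccumulation_groups(
    table: RetentionTable, result: ClusteringResult, labels: pd.Series
) -> pd.Series:
    """Name cluster labels low/medium/high by ranked mean CHI_C18.

    Only defined for a 3-group cut; other group counts get rank names
    ``group_1 < group_2 < ...`` in increasing lipophilicity.
    """
    chi = pd.Series(table.column("chi_c18"), index=table.names)
    means = chi.groupby(labels).mean().sort_values()
    k = len(means)
    names = ["low", "medium", "high"] if k == 3 else [f"group_{i+1}" for i in range(k)]
    mapping = {lab: nm for lab, nm in zip(means.index, names)}
    return labels.map(mapping).rename("bioaccumulation")


def heatmap_export(
    table: RetentionTable,
    clustering: ClusteringResult,
    path,
    csv_path=None,
) -> pd.DataFrame:
    """Export a dendrogram-ordered, auto-scaled heat map (vector graphics)
    plus a companion CSV of exactly the plotted matrix.

    Returns the plotted (leaf-ordered, auto-scaled) DataFrame.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    ordered = clustering.scaled.iloc[clustering.leaf_order]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(ordered) + 1.5))
    sns.heatmap(ordered, cmap="viridis_r", ax=ax, cbar_kws={"label": "auto-scaled index"})
    ax.set_ylabel("")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    if csv_path is None:
        csv_path = str(path).rsplit(".", 1)[0] + ".csv"
    ordered.to_csv(csv_path)
    return ordered
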