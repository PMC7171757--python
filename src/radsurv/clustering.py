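"""Correlation-based feature clustering and table reduction.

Highly correlated features (|Spearman| > 0.90 by default) are grouped by
agglomerative clustering with distance ``1 - |SC|`` and average linkage,
and each cluster is replaced by the average of its members after sign
alignment (members negatively correlated with the cluster anchor are
inverted) and per-member z-scoring. Absolute correlation is used because
anticorrelated features belong in one cluster when inversion-averaging is
the reduction rule.

The cluster map is fitted on the training split only and applied frozen
to validation data; scaling statistics travel with the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TablePreparation",
    "fit_preparation",
    "apply_preparation",
    "spearman_matrix",
    "Cluster",
    "ClusterMap",
    "cluster_features",
    "reduce_table",
    "iterative_reduce",
    "apply_reduction",
    "max_offdiag_abs_spearman",
    "plot_correlation_heatmap",
]


@dataclass
class TablePreparation:
    """Columns retained for clustering plus training medians for imputation.

    Features missing in more than ``max_missing_frac`` of patients are
    dropped, the rest median-imputed; constant columns are dropped because
    their rank correlation is undefined.
    """

    columns: list[str]
    medians: pd.Series
    dropped_missing: list[str]
    dropped_constant: list[str]


def fit_preparation(table: pd.DataFrame, max_missing_frac: float = 0.2) -> TablePreparation:
    missing_frac = table.isna().mean()
    dropped_missing = sorted(missing_frac.index[missing_frac > max_missing_frac])
    kept = table.drop(columns=dropped_missing)
    medians = kept.median()
    filled = kept.fillna(medians)
    constant = sorted(c for c in filled.columns if filled[c].nunique() <= 1)
    columns = [c for c in filled.columns if c not in constant]
    return TablePreparation(columns, medians[columns], dropped_missing, constant)


def apply_preparation(table: pd.DataFrame, prep: TablePreparation) -> pd.DataFrame:
    missing = [c for c in prep.columns if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks prepared columns: {missing}")
    return table[prep.columns].fillna(prep.medians)


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix (average ranks on ties).

    Raises ``ValueError`` naming any constant column, whose rank
    correlation is undefined.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 patients for a rank correlation matrix")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant columns have undefined rank correlation: {constant}")
    cols = list(table.columns)
    rho = stats.spearmanr(table.values).statistic
    rho = np.atleast_2d(rho)
    if rho.shape != (len(cols), len(cols)):  # spearmanr collapses the 2-column case
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cols, columns=cols)


@dataclass
class Cluster:
    members: list[str]
    signs: dict[str, float]
    representative: str  # the anchor's name

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass
class ClusterMap:
    clusters: list[Cluster]
    threshold: float
    member_means: pd.Series | None = None
    member_stds: pd.Series | None = None

    @property
    def all_members(self) -> list[str]:
        return [m for c in self.clusters for m in c.members]

    @property
    def representatives(self) -> list[str]:
        return [c.representative for c in self.clusters]

    def with_scaling(self, table: pd.DataFrame) -> "ClusterMap":
        """Freeze per-member mean/std from *table* (the training split)."""
        members = self.all_members
        stds = table[members].std(ddof=0).replace(0.0, 1.0)
        return replace(self, member_means=table[members].mean(), member_stds=stds)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "clusters": [
                {"representative": c.representative, "members": c.members,
                 "signs": c.signs}
                for c in self.clusters
            ],
        }


def cluster_features(matrix: pd.DataFrame, threshold: float = 0.90) -> ClusterMap:
    """Agglomerative clustering of features at distance ``1 - |SC|``.

    Average linkage, tree cut at ``1 - threshold``. Deterministic: features
    are processed in lexicographic name order. The anchor of a cluster is
    the member with the highest mean |SC| to the other members (ties
    lexicographic); member signs are the sign of their correlation with
    the anchor (near-zero correlation logs a warning and defaults to +1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    cols = sorted(matrix.columns)
    m = matrix.loc[cols, cols].values
    if len(cols) == 1:
        return ClusterMap([Cluster(cols, {cols[0]: 1.0}, cols[0])], threshold)
    dist = 1.0 - np.abs(m)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=1.0 - threshold, criterion="distance")

    clusters: list[Cluster] = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        members = [cols[i] for i in idx]
        if len(members) == 1:
            clusters.append(Cluster(members, {members[0]: 1.0}, members[0]))
            continue
        sub = np.abs(m[np.ix_(idx, idx)])
        mean_abs = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
        anchor_pos = int(np.lexsort((members, -mean_abs))[0])
        anchor = members[anchor_pos]
        signs = {}
        for i, name in zip(idx, members):
            sc = m[i, idx[anchor_pos]]
            if name == anchor:
                signs[name] = 1.0
            elif abs(sc) < 0.1:
                warnings.warn(
                    f"feature {name!r} has |SC| < 0.1 with cluster anchor {anchor!r}; "
                    f"sign set to +1", stacklevel=2)
                signs[name] = 1.0
            else:
                signs[name] = float(np.sign(sc))
        clusters.append(Cluster(members, signs, anchor))
    clusters.sort(key=lambda c: c.representative)
    return ClusterMap(clusters, threshold)


def reduce_table(table: pd.DataFrame, clustermap: ClusterMap) -> pd.DataFrame:
    """Replace each cluster by the mean of its sign-aligned, z-scored
    members; singletons pass through unchanged on their original scale.

    Z-scoring statistics come from ``clustermap`` when frozen via
    :meth:`ClusterMap.with_scaling`, otherwise from *table* itself.
    """
    missing = [m for m in clustermap.all_members if m not in table.columns]
    if missing:
        raise KeyError(f"cluster map covers columns absent from table: {missing}")
    if clustermap.member_means is not None:
        means, stds = clustermap.member_means, clustermap.member_stds
    else:
        members = clustermap.all_members
        means = table[members].mean()
        stds = table[members].std(ddof=0).replace(0.0, 1.0)
    out = {}
    for c in clustermap.clusters:
        if c.is_singleton:
            out[c.representative] = table[c.members[0]].astype(float)
            continue
        z = (table[c.members] - means[c.members]) / stds[c.members]
        aligned = z * pd.Series(c.signs)[c.members]
        out[c.representative] = aligned.mean(axis=1)
    reduced = pd.DataFrame(out, index=table.index)
    return reduced[sorted(reduced.columns)]


def iterative_reduce(table: pd.DataFrame, threshold: float = 0.90,
                     max_passes: int = 20) -> tuple[pd.DataFrame, list[ClusterMap]]:
    """Cluster-and-average until no pair of representatives exceeds the
    correlation threshold.

    A single cluster-and-average pass can leave representative pairs above
    the threshold (averaging creates new columns whose correlations were
    never clustered), so the pass is repeated on its own output until the
    post-reduction audit holds. Convergence is guaranteed: any violating
    pair is merged by the next pass, strictly shrinking the table.

    Returns the reduced table and the list of fitted per-pass maps (each
    carries frozen scaling), replayable on new data with
    :func:`apply_reduction`.
    """
    maps: list[ClusterMap] = []
    current = table
    for _ in range(max_passes):
        corr = spearman_matrix(current)
        cmap = cluster_features(corr, threshold).with_scaling(current)
        maps.append(cmap)
        current = reduce_table(current, cmap)
        if current.shape[1] < 2 or max_offdiag_abs_spearman(current) <= threshold:
            break
    return current, maps


def apply_reduction(table: pd.DataFrame, maps: list[ClusterMap]) -> pd.DataFrame:
    """Replay fitted reduction passes (frozen scaling) on new data."""
    current = table
    for cmap in maps:
        current = reduce_table(current, cmap)
    return current


def max_offdiag_abs_spearman(table: pd.DataFrame) -> float:
    """Largest |Spearman| between distinct columns (the post-reduction audit)."""
    m = spearman_matrix(table).values
    mask = ~np.eye(len(m), dtype=bool)
    return float(np.abs(m[mask]).max()) if mask.any() else 0.0


def plot_correlation_heatmap(matrix: pd.DataFrame, path) -> None:
    """Save a correlation heat map (blue positive, red negative)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(matrix) * 0.12),) * 2)
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("Spearman correlation")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
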