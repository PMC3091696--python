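"""Co-expression clustering of the most differentially expressed genes.

Genes are clustered by complete-linkage agglomeration on 1 - Pearson
correlation distances; samples on 1 - Spearman.  The gene dendrogram is cut
into k named clusters (autogamy 6, reciliation 3, exocytosis 2); cluster names
are assigned by matching each cluster's mean time profile against the
configured archetype templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .datatypes import GeneMatrix


def select_variable_genes(
    values: pd.DataFrame, n: int, samples: list[str] | None = None
) -> list[str]:
    """The n genes with the largest (max - min) log2 signal across the
    designated arrays; ties broken by gene id, lexicographically."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(values):
        raise ValueError(f"requested {n} genes from a matrix of {len(values)}")
    sub = values[samples] if samples is not None else values
    spread = sub.max(axis=1) - sub.min(axis=1)
    order = sorted(spread.index, key=lambda g: (-spread[g], g))
    return order[:n]


def correlation_distance(
    values: pd.DataFrame, axis: str = "genes", method: str = "pearson"
) -> pd.DataFrame:
    """1 - correlation distances between rows (genes) or columns (samples).

    Zero-variance vectors cannot be correlated; they sit at distance 1 from
    everything else (warned) and 0 from themselves.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    mat = values.to_numpy(dtype=float) if axis == "genes" else values.to_numpy(dtype=float).T
    labels = list(values.index) if axis == "genes" else list(values.columns)
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 observations per vector")
    if method == "spearman":
        mat = np.apply_along_axis(rankdata, 1, mat)
    sd = mat.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance vectors set to distance 1"
        )
    centered = mat - mat.mean(axis=1, keepdims=True)
    norm = np.where(degenerate, 1.0, np.sqrt((centered**2).sum(axis=1)))
    unit = centered / norm[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    dist[degenerate, :] = 1.0
    dist[:, degenerate] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class Dendrogram:
    """Agglomeration record: scipy-format merge matrix plus leaf labels."""

    merges: np.ndarray  # (n-1, 4) linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> pd.Series:
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k={k} outside [1, {len(self.labels)}]")
        flat = fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def hclust_complete(distance: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomerative clustering of a distance matrix.

    Inter-cluster distance is the maximum pairwise distance; merge heights
    are therefore non-decreasing.
    """
    arr = distance.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(arr, checks=False)
    merges = linkage(condensed, method="complete")
    return Dendrogram(merges=merges, labels=list(distance.index))


@dataclass
class ClusterSet:
    """Gene -> cluster partition with names and mean +/- sd time profiles."""

    assignments: pd.Series  # gene -> cluster id (1..k)
    names: dict[int, str] = field(default_factory=dict)
    mean_profiles: pd.DataFrame | None = None  # cluster x timepoint
    sd_profiles: pd.DataFrame | None = None

    @property
    def k(self) -> int:
        return self.assignments.nunique()

    def members(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])

    def name_of(self, gene: str) -> str:
        cid = int(self.assignments[gene])
        return self.names.get(cid, f"cluster_{cid}")

    def named_assignments(self) -> pd.Series:
        return self.assignments.map(lambda c: self.names.get(int(c), f"cluster_{c}"))

    def sizes(self) -> pd.Series:
        counts = self.assignments.value_counts().sort_index()
        counts.index = [self.names.get(int(c), f"cluster_{c}") for c in counts.index]
        return counts


def replicate_mean_profiles(gene_matrix: GeneMatrix, genes: list[str]) -> pd.DataFrame:
    """Per gene, replicate-averaged signal at each time point."""
    tps = gene_matrix.timepoints()
    sub = gene_matrix.values.loc[genes]
    order = list(dict.fromkeys(tps))
    return sub.T.groupby(tps).mean().T[order]


def cut_clusters(
    dendrogram: Dendrogram,
    k: int,
    gene_matrix: GeneMatrix | None = None,
    archetypes: dict[str, list[float]] | None = None,
) -> ClusterSet:
    """Cut the gene dendrogram into k clusters and (optionally) name them.

    When a gene matrix and archetype templates are given, each cluster's
    replicate-averaged mean profile is matched to the archetype with which it
    correlates best (greedy, highest correlation first, one archetype per
    cluster); clusters left unmatched keep ordinal names.
    """
    assignments = dendrogram.cut(k)
    clusters = ClusterSet(assignments=assignments)
    if gene_matrix is not None:
        mean, sd = cluster_profiles(clusters, gene_matrix)
        clusters.mean_profiles = mean
        clusters.sd_profiles = sd
        if archetypes:
            clusters.names = _match_archetypes(mean, archetypes)
    return clusters


def _match_archetypes(
    mean_profiles: pd.DataFrame, archetypes: dict[str, list[float]]
) -> dict[int, str]:
    names = sorted(archetypes)
    scores = []
    for cid, profile in mean_profiles.iterrows():
        centered = profile.to_numpy() - profile.mean()
        for name in names:
            tmpl = np.asarray(archetypes[name], dtype=float)
            tmpl = tmpl - tmpl.mean()
            denom = np.linalg.norm(centered) * np.linalg.norm(tmpl)
            r = float(centered @ tmpl / denom) if denom > 0 else -np.inf
            scores.append((r, int(cid), name))
    assigned: dict[int, str] = {}
    used: set[str] = set()
    for r, cid, name in sorted(scores, reverse=True):
        if cid in assigned or name in used or not np.isfinite(r):
            continue
        assigned[cid] = name
        used.add(name)
    return assigned


def cluster_profiles(
    clusters: ClusterSet, gene_matrix: GeneMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and sd over member genes of replicate-averaged time profiles."""
    genes = list(clusters.assignments.index)
    profiles = replicate_mean_profiles(gene_matrix, genes)
    grouped = profiles.groupby(clusters.assignments)
    mean = grouped.mean()
    sd = grouped.std(ddof=0)
    empty = set(range(1, clusters.k + 1)) - set(mean.index)
    if empty:
        warnings.warn(f"empty clusters: {sorted(empty)}")
    return mean, sd


def plot_heatmap(
    gene_matrix: GeneMatrix, clusters: ClusterSet, path
) -> None:
    """Basic (non-normative) expression heatmap ordered by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clusters.assignments.sort_values().index
    data = gene_matrix.values.loc[order]
    data = data.sub(data.mean(axis=1), axis=0)
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(data.to_numpy(), aspect="auto", cmap="coolwarm", interpolation="nearest")
    ax.set_xticks(range(len(data.columns)))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("sample")
    ax.set_ylabel(f"{len(data)} genes in {clusters.k} clusters")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
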