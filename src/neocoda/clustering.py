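"""Hypothesis-free structure in the patient microbiota: hierarchical
clustering in Aitchison geometry, heatmap data export, manual cluster
reassignment, and cluster-wise comparison of clinical parameters.

Samples are clustered on Euclidean distances of their ilr coordinates,
i.e. Aitchison distances between compositions, which makes the result
invariant to per-sample sequencing depth.  Cutting the dendrogram gives
automatic cluster labels; a documented override mechanism records the
occasional judgment call (a sample moved to another cluster on biological
grounds) with full provenance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from .composition import CompositionMatrix, ilr, make_ilr_basis

__all__ = ["Dendrogram", "ClusterAssignment", "hierarchical_cluster",
           "cut_clusters", "apply_overrides", "heatmap_matrix",
           "cluster_compare"]

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus sample labels."""

    samples: list[str]
    linkage_matrix: np.ndarray   # (n-1) x 4 scipy format
    method: str

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 rows")
        if np.any(self.linkage_matrix[:, 2] < 0):
            raise ValueError("negative merge height")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.samples[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage_matrix,
                            columns=["node_a", "node_b", "height", "size"])


@dataclass
class ClusterAssignment:
    """sample id -> cluster label, with per-sample provenance."""

    labels: dict[str, int]
    provenance: dict[str, str] = field(default_factory=dict)
    original: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.labels:
            self.provenance.setdefault(s, "automatic")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": pd.Series(self.labels),
             "provenance": pd.Series(self.provenance),
             "original_cluster": pd.Series(self.original, dtype="Int64")}
        ).rename_axis("sample_id")


def hierarchical_cluster(comp: CompositionMatrix,
                         linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of samples in ilr space.

    Deterministic given input order; scipy breaks merge-distance ties by
    the smallest cluster index.
    """
    if linkage not in ("complete", "ward", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if comp.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    coords = ilr(comp, make_ilr_basis(comp.parts)).coords
    Z = hierarchy.linkage(pdist(coords), method=linkage)
    return Dendrogram(list(comp.samples), Z, linkage)


def cut_clusters(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into k groups; labels 1..k by decreasing group size, ties by
    first appearance in leaf order."""
    n = len(dendrogram.samples)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    raw = hierarchy.fcluster(dendrogram.linkage_matrix, k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # exact-k cut impossible only with duplicate heights; fall back honestly
        logger.warning("maxclust cut produced %d groups for k=%d",
                       len(np.unique(raw)), k)
    leaf_rank = {s: i for i, s in enumerate(dendrogram.leaf_order)}
    sizes = {c: int((raw == c).sum()) for c in np.unique(raw)}
    first_leaf = {
        c: min(leaf_rank[s] for s, r in zip(dendrogram.samples, raw) if r == c)
        for c in sizes
    }
    order = sorted(sizes, key=lambda c: (-sizes[c], first_leaf[c]))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = {s: relabel[c] for s, c in zip(dendrogram.samples, raw)}
    return ClusterAssignment(labels)


def apply_overrides(assignment: ClusterAssignment,
                    overrides: Mapping[str, int]) -> ClusterAssignment:
    """Manually reassign samples to existing cluster labels.

    Each override is recorded (provenance ``manual_override`` plus the
    original label) and logged for the audit trail.
    """
    valid_labels = set(assignment.labels.values())
    labels = dict(assignment.labels)
    prov = dict(assignment.provenance)
    orig = dict(assignment.original)
    for sample, new in overrides.items():
        if sample not in labels:
            raise KeyError(f"override for unknown sample {sample!r}")
        if new not in valid_labels:
            raise ValueError(
                f"override to undefined cluster label {new!r} (have {sorted(valid_labels)})"
            )
        logger.info("manual override: sample %s cluster %d -> %d",
                    sample, labels[sample], new)
        orig[sample] = labels[sample]
        labels[sample] = new
        prov[sample] = "manual_override"
    return ClusterAssignment(labels, prov, orig)


def heatmap_matrix(comp: CompositionMatrix, min_abundance: float = 0.1,
                   dendrogram: Dendrogram | None = None) -> pd.DataFrame:
    """Relative-abundance matrix for heatmap display.

    Keeps genera whose maximum relative abundance across samples is at
    least ``min_abundance`` (inclusive); columns follow dendrogram leaf
    order when a dendrogram is given.
    """
    if not 0 <= min_abundance < 1:
        raise ValueError("min_abundance must be in [0, 1)")
    keep = [j for j in range(comp.n_parts)
            if comp.values[:, j].max() >= min_abundance]
    if not keep:
        raise ValueError(f"no genus reaches relative abundance {min_abundance}")
    frame = pd.DataFrame(comp.values[:, keep].T,
                         index=[comp.parts[j] for j in keep],
                         columns=comp.samples)
    if dendrogram is not None:
        frame = frame[dendrogram.leaf_order]
    return frame


def cluster_compare(values: Mapping[str, float] | pd.Series,
                    assignment: ClusterAssignment,
                    holm: bool = False) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of a clinical parameter
    between clusters.

    Exact enumeration when the combined pair has n <= 20 and no ties,
    normal approximation with tie correction otherwise.  Raw p-values by
    default (descriptive use); ``holm=True`` adds Holm-adjusted values.
    A cluster with no non-missing values is skipped with a warning.
    """
    series = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    by_cluster: dict[int, np.ndarray] = {}
    for c in sorted(set(assignment.labels.values())):
        ids = [s for s, lab in assignment.labels.items() if lab == c]
        v = series.reindex(ids).dropna().to_numpy(float)
        if v.size == 0:
            logger.warning("cluster %d has no non-missing values; skipped", c)
            continue
        by_cluster[c] = v
    if len(by_cluster) < 2:
        raise ValueError("need at least 2 clusters with observations")
    rows = []
    for a, b in itertools.combinations(sorted(by_cluster), 2):
        va, vb = by_cluster[a], by_cluster[b]
        pooled = np.concatenate([va, vb])
        exact = pooled.size <= 20 and len(np.unique(pooled)) == pooled.size
        res = stats.mannwhitneyu(va, vb, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        rows.append({"cluster_a": a, "cluster_b": b, "n_a": va.size,
                     "n_b": vb.size, "statistic": res.statistic,
                     "p_value": res.pvalue,
                     "method": "exact" if exact else "normal_tie_corrected"})
    out = pd.DataFrame(rows)
    if holm:
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        adj = np.empty_like(p)
        m = len(p)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        out["p_holm"] = adj
    return out
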