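"""Hierarchical clustering of analytes in a 2-D embedding, with elbow-based
model selection and per-cluster keyword enrichment.

The module consumes any analyte x 2 coordinate table (a UMAP, a PCA, or any
other embedding computed elsewhere); :func:`pca_embedding` provides a
deterministic fallback for pipelines and tests. Clusters come from
agglomerative (complete-linkage by default) clustering on Euclidean
distances within the embedding, the number of clusters from the elbow of
the within-cluster sum of squares curve, and each cluster is tested for
keyword over-representation against the rest of the map.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .univariate import fisher_enrichment

log = logging.getLogger(__name__)


def _coords(embedding: pd.DataFrame) -> np.ndarray:
    if embedding.shape[1] < 2:
        raise ValueError("embedding needs two coordinate columns")
    return embedding.iloc[:, :2].to_numpy(dtype=float)


def hierarchical_cluster(
    embedding: pd.DataFrame, k: int, method: str = "complete"
) -> pd.DataFrame:
    """Cut an agglomerative tree on embedding distances into ``k`` clusters.

    Returns a table (analyte id from the embedding index, x, y, cluster
    label in 1..k). Duplicated points always share a cluster (they are at
    distance zero), and shuffling row order only relabels the partition.
    """
    pts = _coords(embedding)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(pts):
        raise ValueError(f"k={k} exceeds the {len(pts)} embedded analytes")
    Z = linkage(pdist(pts), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.DataFrame(
        {
            "analyte_id": embedding.index,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "cluster": labels.astype(int),
        }
    )


def _wss(pts: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        sub = pts[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def choose_k_elbow(
    embedding: pd.DataFrame, k_range=range(2, 11), method: str = "complete"
) -> int:
    """Pick k at the elbow of the within-cluster sum-of-squares curve.

    The elbow is the interior k maximizing the discrete second difference
    WSS(k-1) - 2 WSS(k) + WSS(k+1); ties go to the smallest k. When the
    curvature profile is nearly flat (no pronounced elbow) a low-confidence
    warning is logged and the curvature argmax is still returned.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    pts = _coords(embedding)
    if ks[-1] > len(pts) - 1 or ks[0] < 2:
        raise ValueError("k_range must lie within [2, n_analytes - 1]")
    Z = linkage(pdist(pts), method=method)
    wss = {k: _wss(pts, fcluster(Z, t=k, criterion="maxclust")) for k in ks}
    interior = ks[1:-1]
    curv = {k: wss[prev] - 2 * wss[k] + wss[nxt]
            for prev, k, nxt in zip(ks[:-2], interior, ks[2:])}
    best = max(interior, key=lambda k: (curv[k], -k))
    # a pronounced elbow concentrates most of the WSS drop's curvature at one
    # k; smooth single-cluster decays stay well below half the span
    span = max(wss.values()) - min(wss.values())
    if span > 0 and max(curv.values()) < 0.5 * span:
        log.warning("no pronounced elbow in the WSS curve; k=%d is low-confidence", best)
    return int(best)


def cluster_term_enrichment(
    assignments: pd.DataFrame,
    annotation_map: pd.DataFrame,
    enrichment_min: float = 3.0,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """Keyword enrichment of each cluster against the whole embedded map.

    For every cluster, :func:`fisher_enrichment` is run with the cluster as
    foreground and all embedded analytes as background; a term is flagged
    when its enrichment ratio exceeds ``enrichment_min`` and its BH q-value
    is below ``fdr_max`` (defaults 3 and 0.1).
    """
    if annotation_map.empty:
        raise ValueError("annotation map is empty")
    background = list(assignments["analyte_id"])
    tables = []
    for cluster, sub in assignments.groupby("cluster"):
        res = fisher_enrichment(sub["analyte_id"], annotation_map, background)
        res.insert(0, "cluster", cluster)
        tables.append(res)
    out = pd.concat(tables, ignore_index=True)
    out["flagged"] = (out["enrichment_ratio"] > enrichment_min) & (out["q"] < fdr_max)
    return out


def pca_embedding(dataset, impute: bool = True) -> pd.DataFrame:
    """Deterministic 2-D analyte embedding: PCA of the analyte x sample matrix.

    Blocks are concatenated analyte-wise (each analyte becomes a point
    described by its profile over samples); missing values are filled with
    the analyte mean when ``impute`` is set. A plumbing fallback for the
    externally supplied embedding the clustering stage normally consumes.
    """
    from sklearn.decomposition import PCA

    profiles = pd.concat([X.T for X in dataset.blocks.values()], axis=0)
    if impute:
        profiles = profiles.apply(lambda row: row.fillna(row.mean()), axis=1)
    coords = PCA(n_components=2, random_state=0).fit_transform(profiles.to_numpy())
    return pd.DataFrame(coords, index=profiles.index, columns=["x", "y"])
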