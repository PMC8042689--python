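"""Independent checks of a signature: embeddings, clustering baselines.

A candidate signature should segregate held-out, never-seen samples of
the two subtypes in an unsupervised view.  ``tsne_embed`` +
``segregation_accuracy`` implement the low-dimensional check (k-means
with k=2 on the embedding, scored against the true labels under the
best cluster-label permutation); ``hierarchical_cluster`` and
``kmeans_baseline`` provide the naive clustering baselines the transfer
approach is contrasted with.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

__all__ = [
    "tsne_embed",
    "segregation_accuracy",
    "hierarchical_cluster",
    "kmeans_baseline",
]


def tsne_embed(
    features: pd.DataFrame,
    perplexity: float = 20.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """2-D t-SNE embedding of a samples-x-features matrix.

    Deterministic under a fixed ``seed`` (PCA initialisation).  Errors
    when there are fewer than ``perplexity + 1`` samples; warns below
    the customary ``3 * perplexity``.
    """
    n = len(features)
    if n < perplexity + 1:
        raise ValueError(f"need at least perplexity+1={int(perplexity) + 1} samples, got {n}")
    if n < 3 * perplexity:
        warnings.warn(
            f"t-SNE with perplexity {perplexity} on only {n} samples; "
            "recommend >= 3*perplexity samples", UserWarning, stacklevel=2,
        )
    ts = TSNE(n_components=2, perplexity=perplexity, init="pca", random_state=seed)
    xy = ts.fit_transform(features.to_numpy(dtype=float))
    if not np.isfinite(xy).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return pd.DataFrame(xy, index=features.index, columns=["x", "y"])


def kmeans_baseline(
    matrix: pd.DataFrame, k: int = 2, seed: int | None = None, n_init: int = 10
) -> pd.Series:
    """k-means partition (best inertia of ``n_init`` restarts, seeded)."""
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the number of samples ({len(matrix)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(dtype=float))
    return pd.Series(labels, index=matrix.index, name="cluster")


def segregation_accuracy(
    features: pd.DataFrame,
    true_labels: pd.Series | Sequence,
    seed: int | None = None,
) -> dict:
    """How well an unsupervised 2-partition recovers the true two classes.

    Runs k-means (k=2, 10 restarts) on ``features`` — typically a t-SNE
    embedding, but any matrix works — and reports the matching fraction
    under the best of the two cluster-to-label permutations, so the
    accuracy is >= 0.5 by construction.  Misclassified sample ids are
    returned for inspection.
    """
    true = pd.Series(np.asarray(true_labels), index=features.index)
    uniq = true.unique()
    if len(uniq) != 2:
        raise ValueError(f"need exactly two true labels, got {list(uniq)}")
    clusters = kmeans_baseline(features, k=2, seed=seed)
    acc_best, mis_best, perm_best = -1.0, None, None
    for perm in ((uniq[0], uniq[1]), (uniq[1], uniq[0])):
        pred = clusters.map({0: perm[0], 1: perm[1]})
        match = pred == true
        acc = float(match.mean())
        if acc > acc_best:
            acc_best, mis_best, perm_best = acc, list(true.index[~match]), perm
    return {
        "accuracy": acc_best,
        "misclassified": mis_best,
        "clusters": clusters,
        "cluster_to_label": {0: perm_best[0], 1: perm_best[1]},
    }


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "one_minus_pearson",
    method: str = "average",
) -> dict:
    """Agglomerative clustering of rows; default one-minus-Pearson / average linkage.

    Rows that are constant (Pearson undefined) are dropped with a
    warning.  Returns the scipy linkage matrix, the dendrogram leaf
    order, and the ids of the rows retained.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    vals = matrix.to_numpy(dtype=float)
    if metric == "one_minus_pearson":
        sd = vals.std(axis=1)
        keep = sd > 0
        if not keep.any() or keep.sum() < 2:
            raise ValueError("all rows constant under Pearson distance")
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant row(s) for Pearson distance",
                UserWarning, stacklevel=2,
            )
        vals = vals[keep]
        ids = matrix.index[keep]
        corr = np.corrcoef(vals)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrise fp noise
        z = linkage(squareform(dist, checks=False), method=method)
    else:
        ids = matrix.index
        z = linkage(vals, method=method, metric=metric)
    order = leaves_list(z)
    return {"linkage": z, "leaf_order": [ids[i] for i in order], "row_ids": list(ids)}
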