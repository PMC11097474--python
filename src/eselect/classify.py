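"""K-means partition of genes into Spe / Var / Con regulation patterns.

Genes are clustered on their (SPE score, SEL score) pair; with k=3 the
clusters are mapped deterministically to pattern names from centroid
geometry: the lowest-SPE centroid is Con (conserved regulation across
most cell types); of the remaining two, the higher-SEL centroid is Spe
(regulation confined to few cell types) and the lower is Var (many
enhancers that rarely co-occur in the same cell type).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["kmeans_patterns", "label_clusters"]

PATTERNS = ("Spe", "Var", "Con")


def label_clusters(centroids) -> dict[int, str]:
    """Map 3 cluster centroids (on the original score scale) to pattern names.

    Rule: Con = lowest ``spe_score`` centroid; of the remaining two,
    Spe = higher ``sel_score``, Var = lower. Exact ties on the deciding
    coordinate break on the other coordinate, then on cluster index, with
    a warning.
    """
    cent = np.asarray(centroids, dtype=float)
    if cent.shape != (3, 2):
        raise ValueError("label_clusters expects exactly 3 (spe, sel) centroids")

    def argmin_with_tiebreak(order_keys, indices):
        keys = sorted(zip(*order_keys, indices))
        if len(keys) > 1 and keys[0][:-1] == keys[1][:-1]:
            warnings.warn(
                "tied centroids on deciding coordinates; breaking tie by cluster index",
                stacklevel=3,
            )
        return keys[0][-1]

    idx = list(range(3))
    con = argmin_with_tiebreak((cent[:, 0], cent[:, 1]), idx)
    rest = [i for i in idx if i != con]
    spe = argmin_with_tiebreak(
        ([-cent[i, 1] for i in rest], [-cent[i, 0] for i in rest]), rest
    )
    var = next(i for i in rest if i != spe)
    return {con: "Con", spe: "Spe", var: "Var"}


def kmeans_patterns(
    scores: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    restarts: int = 25,
    standardize: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster genes on (spe_score, sel_score) and name the patterns.

    Runs Lloyd's algorithm with ``restarts`` random initialisations keeping
    the best within-cluster sum of squares; the same seed always yields the
    same assignment. Features are z-scored before clustering by default
    (the SEL score's range grows with sqrt(M) and would otherwise dominate).
    With ``k == 3`` clusters are named via :func:`label_clusters`; other k
    get labels ``C0..C{k-1}``.

    Returns
    -------
    (assignments, centroids)
        ``assignments`` has columns ``gene, pattern, cluster_index``;
        ``centroids`` is a ``(k, 2)`` array on the original score scale.
    """
    pts = scores[["spe_score", "sel_score"]].to_numpy(dtype=float)
    n_distinct = len(np.unique(pts, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"need at least {k} distinct (spe_score, sel_score) points, got {n_distinct}"
        )
    if standardize:
        mu = pts.mean(axis=0)
        sigma = pts.std(axis=0)
        sigma[sigma == 0] = 1.0
        feats = (pts - mu) / sigma
    else:
        mu, sigma = np.zeros(2), np.ones(2)
        feats = pts
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(feats)
    centroids = km.cluster_centers_ * sigma + mu
    if k == 3:
        name_of = label_clusters(centroids)
    else:
        name_of = {i: f"C{i}" for i in range(k)}
    out = pd.DataFrame(
        {
            "gene": scores["gene"].to_numpy(),
            "pattern": [name_of[l] for l in labels],
            "cluster_index": labels,
        }
    )
    return out, centroids
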