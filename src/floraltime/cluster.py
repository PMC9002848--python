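"""Z-profile clustering of flowering DEGs and candidate-gene matching.

Each gene's trajectory is its time-point-mean TMM-normalized log2 CPM,
standardized across the four time points: Z = (X - mu) / sigma.  Flowering
DEGs are K-means clustered on these Z-profiles (Euclidean distance); the
number of clusters is chosen by majority vote of an internal-validity index
panel (silhouette, Calinski-Harabasz, Davies-Bouldin, gap statistic).
Uncharacterized DEGs whose Z-profile has Pearson r > 0.99 with a cluster's
average Z-profile are nominated as novel flowering-gene candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

from .data_io import CountMatrix
from .normalize import NormalizationFactors, log_cpm

logger = logging.getLogger("floraltime")

R_THRESHOLD = 0.99


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series            # gene_id -> cluster label (0..k-1)
    centroids: pd.DataFrame           # k x time points, mean member z
    index_votes: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Z-profiles
# ---------------------------------------------------------------------------

def timepoint_mean_log_cpm(cm: CountMatrix, nf: NormalizationFactors,
                           prior_count: float = 2.0) -> pd.DataFrame:
    """Per-gene mean log2 CPM per time point (genes x time points)."""
    lc = log_cpm(cm, nf, prior_count)
    return pd.DataFrame({t: lc.iloc[:, cols].mean(axis=1)
                         for t, cols in cm.groups().items()})


def zscore(profiles: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each gene's trajectory: Z = (X - mu) / sigma across its
    time points (sample SD by default).

    Flat profiles (sigma = 0) are excluded from the result and logged —
    they carry no shape information to cluster or match.
    """
    x = profiles.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sigma = x.std(axis=1, ddof=ddof, keepdims=True)
    flat = sigma[:, 0] <= 0
    if flat.any():
        logger.info("zscore: excluding %d flat profile(s)", int(flat.sum()))
    z = (x[~flat] - mu[~flat]) / sigma[~flat]
    return pd.DataFrame(z, index=profiles.index[~flat], columns=profiles.columns)


# ---------------------------------------------------------------------------
# k selection and K-means
# ---------------------------------------------------------------------------

def _kmeans(x: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    return KMeans(n_clusters=k, init="random", n_init=n_init,
                  random_state=seed % (2 ** 32)).fit(x)


def _pooled_within_ss(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic_k(x: np.ndarray, ks: list[int], rng: np.random.Generator,
                    n_refs: int = 50, n_init: int = 5) -> int:
    """Gap statistic (uniform reference over the bounding box).

    Picks the smallest k with gap(k) >= gap(k+1) - s(k+1); if no k
    satisfies the rule, the k maximizing the gap.
    """
    lo, hi = x.min(axis=0), x.max(axis=0)
    log_w = []
    ref_log_w = np.empty((len(ks), n_refs))
    for i, k in enumerate(ks):
        km = _kmeans(x, k, int(rng.integers(2 ** 31)), n_init)
        log_w.append(np.log(_pooled_within_ss(x, km.labels_)))
        for b in range(n_refs):
            ref = rng.uniform(lo, hi, size=x.shape)
            km_ref = _kmeans(ref, k, int(rng.integers(2 ** 31)), n_init)
            ref_log_w[i, b] = np.log(_pooled_within_ss(ref, km_ref.labels_))
    gap = ref_log_w.mean(axis=1) - np.asarray(log_w)
    s = ref_log_w.std(axis=1, ddof=0) * np.sqrt(1.0 + 1.0 / n_refs)
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return ks[i]
    return ks[int(np.argmax(gap))]


def select_k_and_cluster(z: pd.DataFrame, k_range: tuple[int, int] = (2, 10),
                         seed: int = 0, restarts: int = 50,
                         gap_refs: int = 50) -> ClusterModel:
    """Choose k by index-panel majority vote and fit the final K-means.

    Panel: silhouette (max), Calinski-Harabasz (max), Davies-Bouldin (min),
    gap statistic (Tibshirani rule).  Ties in the vote go to the smaller k.
    The final model is refit at the chosen k; clusters are relabelled in a
    deterministic order (by centroid trajectory) so results do not depend
    on K-means' internal label order.
    """
    x = z.to_numpy(float)
    k_min, k_max = k_range
    if x.shape[0] < k_max + 1:
        raise ValueError(f"need at least {k_max + 1} genes to scan k in "
                         f"[{k_min}, {k_max}]; got {x.shape[0]}")
    rng = np.random.default_rng(seed)
    ks = list(range(k_min, k_max + 1))
    fits = {k: _kmeans(x, k, int(rng.integers(2 ** 31)), restarts) for k in ks}
    sil = {k: silhouette_score(x, fits[k].labels_) for k in ks}
    ch = {k: calinski_harabasz_score(x, fits[k].labels_) for k in ks}
    db = {k: davies_bouldin_score(x, fits[k].labels_) for k in ks}
    votes = {
        "silhouette": min(k for k in ks if sil[k] == max(sil.values())),
        "calinski_harabasz": min(k for k in ks if ch[k] == max(ch.values())),
        "davies_bouldin": min(k for k in ks if db[k] == min(db.values())),
        "gap": gap_statistic_k(x, ks, rng, n_refs=gap_refs),
    }
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index
    k = int(min(top))
    final = _kmeans(x, k, seed % (2 ** 32), restarts)
    labels = final.labels_
    centroids = np.vstack([x[labels == c].mean(axis=0) for c in range(k)])
    order = np.lexsort(centroids.T[::-1])  # sort clusters by centroid values
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in labels])
    centroids = centroids[order]
    return ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=z.index, name="cluster"),
        centroids=pd.DataFrame(centroids, columns=z.columns,
                               index=pd.RangeIndex(k, name="cluster")),
        index_votes=votes,
    )


# ---------------------------------------------------------------------------
# Candidate matching
# ---------------------------------------------------------------------------

def match_candidates(model: ClusterModel, z_candidates: pd.DataFrame,
                     threshold: float = R_THRESHOLD) -> pd.DataFrame:
    """Correlate candidate Z-profiles against cluster average Z-profiles.

    Returns one row per candidate gene (best_cluster, r, is_candidate),
    sorted by r descending; is_candidate iff max-over-clusters r exceeds
    ``threshold``.  The candidate pool must exclude the genes that built
    the centroids.
    """
    cen = model.centroids.to_numpy(float)
    if np.any(cen.std(axis=1) <= 0):
        raise ValueError("degenerate centroid (zero variance across time points)")
    overlap = set(z_candidates.index) & set(model.assignments.index)
    if overlap:
        raise ValueError(f"candidate pool overlaps clustered genes: {sorted(overlap)[:5]}")
    x = z_candidates.to_numpy(float)
    xs = (x - x.mean(axis=1, keepdims=True))
    xs /= np.linalg.norm(xs, axis=1, keepdims=True)
    cs = (cen - cen.mean(axis=1, keepdims=True))
    cs /= np.linalg.norm(cs, axis=1, keepdims=True)
    r = xs @ cs.T                      # Pearson r, candidates x clusters
    best = np.argmax(r, axis=1)
    best_r = r[np.arange(len(x)), best]
    out = pd.DataFrame({
        "gene_id": z_candidates.index,
        "best_cluster": best,
        "r": best_r,
        "is_candidate": best_r > threshold,
    }).sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)
    return out
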