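"""Connectivity-based subject subtyping.

Subjects are clustered on vectorized seed-connectivity maps: Euclidean
distances, agglomerative hierarchical clustering, and a majority vote over
internal cluster-validity indices to choose the number of clusters.
Per-subtype contrasts against controls and per-subtype transcriptomic
enrichment reuse the connectivity and enrichment modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

from .connectivity import ConnectivityMap, group_tmap
from .enrichment import (EnrichmentResult, GeneExpressionAtlas, GeneSet,
                         decode_genes, donor_slopes, enrich, fdr_bh)

__all__ = ["ClusterSolution", "distance_matrix", "hierarchical_cluster",
           "select_k", "majority_vote", "subtype_contrasts",
           "subtype_enrichment", "DEFAULT_INDICES"]

DEFAULT_INDICES = ("silhouette", "calinski_harabasz", "davies_bouldin",
                   "dunn", "c_index", "gap")


@dataclass
class ClusterSolution:
    labels: np.ndarray        # per-subject cluster ids, 1..k
    k: int
    linkage: str
    index_votes: dict | None = None


def distance_matrix(M: np.ndarray) -> np.ndarray:
    """Subject x subject Euclidean distance matrix of map rows."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("need a subject x feature matrix")
    return squareform(pdist(M, metric="euclidean"))


def _as_condensed(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        return D
    return squareform(D, checks=False)


def hierarchical_cluster(D: np.ndarray, k: int,
                         method: str = "complete") -> ClusterSolution:
    """Agglomerative clustering of a distance matrix cut at k clusters."""
    cond = _as_condensed(D)
    n = squareform(cond, checks=False).shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    Z = linkage(cond, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterSolution(labels=labels, k=int(len(np.unique(labels))),
                           linkage=method)


def _dunn(D: np.ndarray, labels: np.ndarray) -> float:
    ids = np.unique(labels)
    intra = 0.0
    inter = np.inf
    for i, a in enumerate(ids):
        ma = labels == a
        da = D[np.ix_(ma, ma)]
        if da.size > 1:
            intra = max(intra, da.max())
        for b in ids[i + 1:]:
            mb = labels == b
            inter = min(inter, D[np.ix_(ma, mb)].min())
    return inter / intra if intra > 0 else np.inf


def _c_index(D: np.ndarray, labels: np.ndarray) -> float:
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    within = labels[iu[0]] == labels[iu[1]]
    nw = int(within.sum())
    if nw == 0 or nw == d.size:
        return np.nan
    s = np.sort(d)
    sw = d[within].sum()
    smin = s[:nw].sum()
    smax = s[-nw:].sum()
    return (sw - smin) / (smax - smin) if smax > smin else np.nan

def _gap(M: np.ndarray, labels_by_k: dict[int, np.ndarray],
         rng: np.random.Generator, n_ref: int = 10,
         method: str = "complete") -> dict[int, float]:
    """Gap statistic: log within-dispersion vs. uniform reference draws."""
    def log_wk(X, labels):
        w = 0.0
        for c in np.unique(labels):
            block = X[labels == c]
            if block.shape[0] > 1:
                w += ((block - block.mean(axis=0)) ** 2).sum()
        return np.log(w) if w > 0 else -np.inf

    lo, hi = M.min(axis=0), M.max(axis=0)
    ks = sorted(labels_by_k)
    ref_logs = {k: [] for k in ks}
    for _ in range(n_ref):
        ref = rng.uniform(lo, hi, size=M.shape)
        Dref = pdist(ref)
        Zref = linkage(Dref, method=method)
        for k in ks:
            lab = fcluster(Zref, t=k, criterion="maxclust")
            ref_logs[k].append(log_wk(ref, lab))
    return {k: float(np.mean(ref_logs[k]) - log_wk(M, labels_by_k[k]))
            for k in ks}


def majority_vote(nominations) -> int:
    """Mode of per-index best-k nominations; ties broken toward smaller k.

    Accepts either a sequence of nominated k values or a mapping
    {k: vote count}.
    """
    if isinstance(nominations, dict):
        tally = {int(k): int(v) for k, v in nominations.items()}
    else:
        tally = {}
        for k in nominations:
            tally[int(k)] = tally.get(int(k), 0) + 1
    if not tally:
        raise ValueError("no nominations")
    best_votes = max(tally.values())
    return min(k for k, v in tally.items() if v == best_votes)


def select_k(M: np.ndarray | None = None, D: np.ndarray | None = None,
             k_candidates=range(2, 11), indices=DEFAULT_INDICES,
             method: str = "complete", seed: int = 0) -> tuple[int, dict]:
    """Choose the number of clusters by index majority vote.

    Each cluster-validity index nominates its best k over the candidate
    range; the chosen k is the most nominated one (ties toward smaller k).
    Feature-space indices (Calinski-Harabasz, Davies-Bouldin, gap) are
    skipped when only a distance matrix is supplied.
    """
    if M is None and D is None:
        raise ValueError("provide subject maps M and/or distances D")
    if M is not None:
        M = np.asarray(M, dtype=float)
    if D is None:
        D = distance_matrix(M)
    D = np.asarray(D, dtype=float)
    ks = [int(k) for k in k_candidates]
    n = D.shape[0]
    ks = [k for k in ks if 2 <= k < n]
    if not ks:
        raise ValueError("no usable candidate k")
    labels_by_k = {k: hierarchical_cluster(D, k, method).labels for k in ks}
    needs_m = {"calinski_harabasz", "davies_bouldin", "gap"}
    scores: dict[str, dict[int, float]] = {}
    rng = np.random.default_rng(seed)
    for name in indices:
        if name in needs_m and M is None:
            continue
        if name == "gap":
            scores[name] = _gap(M, labels_by_k, rng, method=method)
            continue
        vals = {}
        for k in ks:
            lab = labels_by_k[k]
            if len(np.unique(lab)) < 2:
                vals[k] = np.nan
                continue
            if name == "silhouette":
                vals[k] = silhouette_score(D, lab, metric="precomputed")
            elif name == "calinski_harabasz":
                vals[k] = calinski_harabasz_score(M, lab)
            elif name == "davies_bouldin":
                vals[k] = davies_bouldin_score(M, lab)
            elif name == "dunn":
                vals[k] = _dunn(D, lab)
            elif name == "c_index":
                vals[k] = _c_index(D, lab)
            else:
                raise ValueError(f"unknown index {name!r}")
        scores[name] = vals
    minimize = {"davies_bouldin", "c_index"}
    nominations = []
    for name, vals in scores.items():
        usable = {k: v for k, v in vals.items() if np.isfinite(v)}
        if not usable:
            continue
        pick = (min if name in minimize else max)(usable, key=usable.get)
        nominations.append(pick)
    if len(nominations) < 2:
        raise ValueError("fewer than 2 usable cluster-validity indices")
    votes: dict[int, int] = {}
    for k in nominations:
        votes[k] = votes.get(k, 0) + 1
    return majority_vote(votes), votes


def subtype_contrasts(M_cases: np.ndarray, labels: ClusterSolution | np.ndarray,
                      M_controls: np.ndarray) -> dict[int, ConnectivityMap]:
    """Per-cluster pooled-t contrast of case maps against control maps."""
    lab = labels.labels if isinstance(labels, ClusterSolution) else np.asarray(labels)
    M_cases = np.asarray(M_cases, dtype=float)
    M_controls = np.asarray(M_controls, dtype=float)
    if lab.shape[0] != M_cases.shape[0]:
        raise ValueError("one label per case subject required")
    out = {}
    for c in np.unique(lab):
        block = M_cases[lab == c]
        if block.shape[0] < 2:
            raise ValueError(f"cluster {c} has fewer than 2 subjects")
        out[int(c)] = group_tmap(block, M_controls)
    return out


def subtype_enrichment(per_cluster_maps: dict[int, ConnectivityMap],
                       atlas: GeneExpressionAtlas, target: GeneSet,
                       q_threshold: float = 0.05) -> dict[int, EnrichmentResult]:
    """Decode each subtype's contrast map and test target-set enrichment.

    Benjamini-Hochberg correction is applied across the per-cluster
    hypergeometric p-values.
    """
    results: dict[int, EnrichmentResult] = {}
    for c, cmap in sorted(per_cluster_maps.items()):
        vals = cmap.values if isinstance(cmap, ConnectivityMap) else np.asarray(cmap)
        slopes = donor_slopes(atlas, vals)
        decoded = decode_genes(slopes, q_threshold=q_threshold)
        genes = set(decoded.genes) & target.universe
        results[int(c)] = enrich(genes, target)
    qs = fdr_bh([r.p_hypergeometric for r in results.values()])
    for (c, r), q in zip(sorted(results.items()), qs):
        r.q = float(q)
    return results
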