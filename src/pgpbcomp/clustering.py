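"""Habitat clustering: PAM k-medoids on phylogenetic distances with
silhouette-based model selection, complete-linkage clustering on per-Mb
feature profiles, and habitat composition / concordance summaries.

PAM here is the classic Kaufman-Rousseeuw partitioning around medoids:
a greedy BUILD phase followed by best-improvement SWAP sweeps, run on a
precomputed distance matrix (typically cophenetic distances from the strain
phylogeny). The number of clusters is chosen by scanning k and taking the
highest mean silhouette coefficient; silhouette is undefined at k=1, so the
scan starts at 2.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score

from pgpbcomp._util import pct


@dataclass
class ClusterAssignment:
    """A strain -> cluster mapping with medoids and fit diagnostics.

    Clusters are numbered 1..k in order of sorted medoid label (PAM) or
    first appearance (hierarchical); ``objective`` is the total distance of
    each point to its cluster medoid.
    """

    labels: list[str]
    cluster_of: dict[str, int]
    medoids: dict[int, str]
    k: int
    objective: float
    mean_silhouette: float | None = None

    def membership(self, order: Sequence[str] | None = None) -> np.ndarray:
        ids = list(order) if order is not None else self.labels
        return np.array([self.cluster_of[i] for i in ids])

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in self.medoids}
        for lab in self.labels:
            out[self.cluster_of[lab]].append(lab)
        return out


def _argbest(values: np.ndarray, labels: Sequence[str], minimize: bool = True) -> int:
    """Index of the extreme value; exact ties broken by smallest label."""
    best = values.min() if minimize else values.max()
    tied = np.flatnonzero(values == best)
    if len(tied) == 1:
        return int(tied[0])
    return int(min(tied, key=lambda i: labels[i]))


#: exhaustive medoid search is used when C(n, k) is at most this many sets;
#: above it the BUILD + SWAP heuristic takes over.
_EXACT_SEARCH_LIMIT = 10_000


def pam(dist: DistanceMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Partitioning around medoids (exact on small instances, else
    BUILD + best-improvement SWAP).

    When the number of candidate medoid sets C(n, k) is small the global
    optimum is found by enumeration (single-swap local search provably
    misses it on some instances); larger instances use the classic
    Kaufman-Rousseeuw BUILD phase plus SWAP sweeps, whose objective is
    non-increasing and which stop at the first sweep with no strictly
    improving swap. Deterministic either way: exact ties are broken
    lexicographically by strain id, so the seed only matters through that
    ordering (kept in the signature for interface stability).
    """
    labels = list(dist.ids)
    D = np.asarray(dist.data, dtype=float)
    n = len(labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")

    if k == n:
        medoid_idx = list(range(n))
    elif math.comb(n, k) <= _EXACT_SEARCH_LIMIT:
        # enumerate candidate sets in label-lexicographic order; keeping
        # strictly better objectives makes ties resolve to the smallest set
        order = sorted(range(n), key=lambda i: labels[i])
        best_obj = np.inf
        best_set: tuple[int, ...] | None = None
        for combo in itertools.combinations(order, k):
            obj = D[list(combo)].min(axis=0).sum()
            if obj < best_obj:
                best_obj, best_set = obj, combo
        assert best_set is not None
        medoid_idx = list(best_set)
    else:
        # BUILD: first medoid minimizes total distance; each subsequent
        # medoid maximizes the reduction in nearest-medoid distance.
        colsums = D.sum(axis=0)
        medoid_idx = [_argbest(colsums, labels)]
        d_nearest = D[medoid_idx[0]].copy()
        while len(medoid_idx) < k:
            gains = np.where(
                np.isin(np.arange(n), medoid_idx),
                -np.inf,
                np.maximum(d_nearest[None, :] - D, 0.0).sum(axis=1),
            )
            nxt = _argbest(gains, labels, minimize=False)
            medoid_idx.append(nxt)
            d_nearest = np.minimum(d_nearest, D[nxt])

        # SWAP sweeps: evaluate every (medoid, non-medoid) exchange and
        # apply the best strictly improving one until none exists.
        while True:
            med = np.array(sorted(medoid_idx, key=lambda i: labels[i]))
            DM = D[med]  # k x n
            nearest_pos = DM.argmin(axis=0)
            d1 = DM[nearest_pos, np.arange(n)]
            if k > 1:
                part = np.partition(DM, 1, axis=0)
                d2 = part[1]
            else:
                d2 = np.full(n, np.inf)
            current = d1.sum()
            others = np.array([i for i in range(n) if i not in set(med.tolist())])
            best_delta = 0.0
            best_swap: tuple[int, int] | None = None
            for pos in range(k):
                mask = nearest_pos == pos
                Dh = D[others]  # (n-k) x n
                cost = np.where(
                    mask[None, :],
                    np.minimum(Dh, d2[None, :]),
                    np.minimum(Dh, d1[None, :]),
                ).sum(axis=1)
                deltas = cost - current
                j = _argbest(deltas, [labels[h] for h in others])
                if deltas[j] < best_delta - 1e-12 or (
                    best_swap is not None
                    and abs(deltas[j] - best_delta) <= 1e-12
                    and deltas[j] < 0
                    and (labels[med[pos]], labels[others[j]])
                    < (labels[best_swap[0]], labels[best_swap[1]])
                ):
                    best_delta = deltas[j]
                    best_swap = (int(med[pos]), int(others[j]))
            if best_swap is None or best_delta >= -1e-12:
                break
            medoid_idx = [i for i in medoid_idx if i != best_swap[0]]
            medoid_idx.append(best_swap[1])

    med = sorted(medoid_idx, key=lambda i: labels[i])
    DM = D[med]
    nearest_pos = DM.argmin(axis=0)
    cluster_of = {labels[i]: int(nearest_pos[i]) + 1 for i in range(n)}
    for c, m in enumerate(med, start=1):  # medoids always own their cluster
        cluster_of[labels[m]] = c
    medoids = {c: labels[m] for c, m in enumerate(med, start=1)}
    objective = float(
        sum(D[i, med[cluster_of[labels[i]] - 1]] for i in range(n))
    )
    return ClusterAssignment(labels, cluster_of, medoids, k, objective)


def mean_silhouette(dist: DistanceMatrix, assignment: ClusterAssignment) -> float:
    """Unweighted mean silhouette coefficient over all points.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean intra-cluster
    distance excluding i and b(i) the smallest mean distance to another
    cluster; singleton clusters contribute 0. Undefined for k < 2 or k = n.
    """
    n = len(dist.ids)
    if assignment.k < 2 or assignment.k >= n:
        raise ValueError("silhouette is undefined unless 2 <= k <= n-1")
    y = assignment.membership(order=list(dist.ids))
    return float(silhouette_score(np.asarray(dist.data), y, metric="precomputed"))


@dataclass
class KSelection:
    k_best: int
    curve: list[tuple[int, float]]
    best_assignment: ClusterAssignment


def select_k(
    dist: DistanceMatrix,
    k_min: int = 2,
    k_max: int = 20,
    seed: int = 0,
) -> KSelection:
    """Scan k, fit PAM at each, and pick the silhouette-maximizing k.

    Ties go to the smaller k. ``k_max`` is clipped to n-1 (with a warning)
    because silhouette is undefined when every point is its own cluster.
    """
    n = len(dist.ids)
    if k_min < 2:
        raise ValueError("k_min must be >= 2 (silhouette undefined at k=1)")
    if k_max > n - 1:
        warnings.warn(f"k_max clipped from {k_max} to n-1 = {n - 1}", stacklevel=2)
        k_max = n - 1
    if k_max < k_min:
        raise ValueError("k_max < k_min after clipping")
    curve: list[tuple[int, float]] = []
    best: tuple[int, float, ClusterAssignment] | None = None
    for k in range(k_min, k_max + 1):
        a = pam(dist, k, seed=seed)
        s = mean_silhouette(dist, a)
        a.mean_silhouette = s
        curve.append((k, s))
        if best is None or s > best[1]:
            best = (k, s, a)
    assert best is not None
    return KSelection(best[0], curve, best[2])


def hclust_complete(features, n_clusters: int) -> ClusterAssignment:
    """Complete-linkage agglomerative clustering on feature vectors.

    ``features`` is a strains x feature-classes table (DataFrame or
    FeatureTable), typically per-Mb normalized; the metric is Euclidean.
    Cluster medoids are the within-cluster distance-sum minimizers.
    """
    df = getattr(features, "df", features)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    X = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    labels = list(df.index)
    n = len(labels)
    if n_clusters > n:
        raise ValueError("n_clusters exceeds number of strains")
    if n == 1 or n_clusters == 1:
        flat = np.ones(n, dtype=int)
    else:
        Z = linkage(X, method="complete", metric="euclidean")
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber clusters 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    for c in flat:
        if c not in remap:
            remap[c] = len(remap) + 1
    y = np.array([remap[c] for c in flat])
    k = int(y.max())
    cluster_of = {labels[i]: int(y[i]) for i in range(n)}
    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(X)) if n > 1 else np.zeros((1, 1))
    medoids: dict[int, str] = {}
    objective = 0.0
    for c in range(1, k + 1):
        idx = np.flatnonzero(y == c)
        sub = D[np.ix_(idx, idx)]
        sums = sub.sum(axis=1)
        m = idx[_argbest(sums, [labels[i] for i in idx])]
        medoids[c] = labels[m]
        objective += float(D[np.ix_([m], idx)].sum())
    sil = None
    if 2 <= k <= n - 1:
        sil = float(silhouette_score(D, y, metric="precomputed"))
    return ClusterAssignment(labels, cluster_of, medoids, k, objective, sil)


def cluster_composition(
    assignment: ClusterAssignment, habitats: Mapping[str, str]
) -> pd.DataFrame:
    """Per-cluster habitat counts, totals and percentage shares.

    Percentages are 100 x count / cluster total, rounded half-up to two
    decimals (the convention of printed tables).
    """
    missing = [s for s in assignment.labels if s not in habitats]
    if missing:
        raise ValueError(f"habitat missing for strains: {missing[:5]}")
    habs = sorted({habitats[s] for s in assignment.labels})
    rows = []
    for c in sorted(assignment.medoids):
        members = [s for s in assignment.labels if assignment.cluster_of[s] == c]
        counts = {h: sum(1 for s in members if habitats[s] == h) for h in habs}
        total = len(members)
        row: dict[str, object] = {"cluster": c, **counts, "total": total}
        for h in habs:
            row[f"{h}_pct"] = pct(counts[h], total)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


@dataclass
class ConcordanceSummary:
    """Majority-habitat concordance of a clustering."""

    majority_of_cluster: dict[int, str]
    concordant_n: dict[str, int]
    concordant_pct_of_all: dict[str, float]
    total: int


def habitat_concordance(
    assignment: ClusterAssignment, habitats: Mapping[str, str]
) -> ConcordanceSummary:
    """Count strains whose habitat matches their cluster's majority habitat.

    Each cluster is assigned its most frequent habitat (ties broken toward
    the lexicographically smaller habitat name); a strain is concordant iff
    its own habitat equals that majority. Percentages use ALL strains as the
    denominator, rounded half-up to two decimals.
    """
    missing = [s for s in assignment.labels if s not in habitats]
    if missing:
        raise ValueError(f"habitat missing for strains: {missing[:5]}")
    total = len(assignment.labels)
    habs = sorted({habitats[s] for s in assignment.labels})
    majority: dict[int, str] = {}
    for c, members in assignment.cluster_members().items():
        counts = {h: sum(1 for s in members if habitats[s] == h) for h in habs}
        best = max(counts.values())
        majority[c] = min(h for h, v in counts.items() if v == best)
    conc = {h: 0 for h in habs}
    for s in assignment.labels:
        if habitats[s] == majority[assignment.cluster_of[s]]:
            conc[habitats[s]] += 1
    pcts = {h: pct(conc[h], total) for h in habs}
    return ConcordanceSummary(majority, conc, pcts, total)
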