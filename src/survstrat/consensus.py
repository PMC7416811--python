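"""Resampling-based consensus hierarchical clustering.

For each candidate k, patients are repeatedly subsampled, clustered by
agglomerative hierarchical clustering, and the fraction of resamples in
which each pair lands in the same cluster (among resamples where both were
drawn) forms the consensus matrix.  The empirical CDF of consensus values,
its area A(k) and the relative area gain Delta(k) drive the choice of k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "ConsensusResult",
    "ConsensusClustering",
    "hierarchical_cluster",
    "agglomerate",
    "cut_merges",
    "consensus_cluster",
    "consensus_cdf",
    "delta_area",
    "select_k",
    "stability_metrics",
    "CDF_GRID",
]

#: Fixed 101-point evaluation grid for consensus CDFs; a shared grid makes
#: areas bit-reproducible across implementations.
CDF_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


# ---------------------------------------------------------------------------
# agglomerative hierarchical clustering (deterministic tie-break)
# ---------------------------------------------------------------------------

def _check_distance_matrix(D):
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    return D


def agglomerate(D, linkage: str = "average"):
    """Full agglomerative merge sequence on a distance matrix.

    Returns a list of ``(i, j, height, size)`` merges, where clusters are
    identified by their smallest member index (the merged cluster keeps
    ``min(i, j)``).  Ties are broken deterministically by merging the
    lexicographically smallest index pair.  Linkage updates follow
    Lance-Williams: 'average' (UPGMA), 'complete', or 'ward' (on squared
    distances, heights reported on the distance scale).
    """
    D = _check_distance_matrix(D).copy()
    n = D.shape[0]
    if linkage not in ("average", "complete", "ward"):
        raise ValueError("linkage must be 'average', 'complete' or 'ward'")
    squared = linkage == "ward"
    if squared:
        D = D**2
    work = D.copy()
    # mask the lower triangle and diagonal so a row-major argmin picks the
    # lexicographically smallest (i, j), i < j, among tied minima
    iu = np.tril_indices(n)
    work[iu] = np.inf
    sizes = np.ones(n, dtype=int)
    active = np.ones(n, dtype=bool)
    merges = []
    for _ in range(n - 1):
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        h = work[i, j]
        ni, nj = sizes[i], sizes[j]
        # Lance-Williams update of distances from the new cluster (kept at
        # index i) to every other active cluster k
        others = np.flatnonzero(active)
        others = others[(others != i) & (others != j)]
        d_ik = np.where(others < i, work[others, i], work[i, others])
        d_jk = np.where(others < j, work[others, j], work[j, others])
        if linkage == "average":
            new = (ni * d_ik + nj * d_jk) / (ni + nj)
        elif linkage == "complete":
            new = np.maximum(d_ik, d_jk)
        else:  # ward on squared distances
            nk = sizes[others]
            tot = ni + nj + nk
            new = ((ni + nk) * d_ik + (nj + nk) * d_jk - nk * h) / tot
        lo = np.minimum(others, i)
        hi = np.maximum(others, i)
        work[lo, hi] = new
        work[others, j] = np.inf
        work[j, others] = np.inf
        work[min(i, j), max(i, j)] = np.inf
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
        sizes[i] = ni + nj
        merges.append((i, j, float(np.sqrt(h)) if squared else float(h), int(sizes[i])))
    return merges


def cut_merges(merges, n: int, k: int):
    """Labels 1..k after replaying the first n-k merges.

    Cluster labels are ordered by each cluster's smallest member index.
    """
    if not (1 <= k <= n):
        raise ValueError("k must lie in [1, n]")
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, _, _ in merges[: n - k]:
        parent[find(j)] = find(i)
    roots = np.array([find(a) for a in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    # np.unique sorts roots ascending; roots are smallest member indices
    return labels + 1


def hierarchical_cluster(distance_matrix, linkage: str = "average", k: int = 2):
    """Agglomerative clustering of a distance matrix, cut at k groups."""
    D = _check_distance_matrix(distance_matrix)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError("k must lie in [1, n]")
    merges = agglomerate(D, linkage)
    return cut_merges(merges, n, k)


# ---------------------------------------------------------------------------
# consensus machinery
# ---------------------------------------------------------------------------

def _profile_distances(X, distance: str):
    X = np.asarray(X, dtype=float)
    if distance == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif distance == "pearson":
        if X.shape[1] < 2:
            raise ValueError("pearson distance needs at least 2 profile columns")
        D = 1.0 - np.corrcoef(X)
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
    else:
        raise ValueError("distance must be 'euclidean' or 'pearson'")
    return D


def consensus_cdf(consensus_matrix, grid=CDF_GRID):
    """Empirical CDF of the n(n-1)/2 upper-triangular consensus entries."""
    M = np.asarray(consensus_matrix, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("consensus CDF needs at least 2 items")
    vals = M[np.triu_indices(n, k=1)]
    return np.searchsorted(np.sort(vals), grid, side="right") / vals.size


def delta_area(cdfs, grid=CDF_GRID):
    """Per-k relative gain in area under the consensus CDF.

    ``cdfs`` is a mapping k -> CDF (consecutive k ascending, starting at 2).
    A(k) is the trapezoidal area under the CDF; Delta(2) = A(2) and
    Delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2.
    """
    ks = sorted(cdfs)
    if len(ks) < 2:
        raise ValueError("delta_area needs at least 2 values of k")
    if ks[0] != 2 or ks != list(range(2, 2 + len(ks))):
        raise ValueError("k values must be consecutive ascending starting at 2")
    areas = {k: float(np.trapezoid(np.asarray(cdfs[k], dtype=float), grid)) for k in ks}
    deltas = {}
    for k in ks:
        if k == 2:
            deltas[k] = areas[k]
        else:
            prev = areas[k - 1]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    return areas, deltas


def select_k(delta_areas: dict, tau: float = 0.1) -> int:
    """Delta-area rule for the number of clusters.

    Picks the k >= 3 with the largest Delta(k) provided that maximum exceeds
    ``tau``; otherwise 2.  Ties go to the smaller k (parsimony).
    """
    ks = sorted(delta_areas)
    cand = [k for k in ks if k >= 3]
    if not cand:
        return min(ks)
    best = max(cand, key=lambda k: (delta_areas[k], -k))
    return best if delta_areas[best] > tau else 2


def stability_metrics(consensus_matrix, assignment):
    """Cluster consensus and item consensus.

    ``cluster_consensus[c]`` is the mean consensus over distinct pairs within
    cluster c (NaN with a warning for singletons); ``item_consensus[i, c]``
    the mean consensus of item i with the members of cluster c (excluding i
    itself when i belongs to c).
    """
    M = np.asarray(consensus_matrix, dtype=float)
    labels = np.asarray(assignment)
    clusters = np.unique(labels)
    n = M.shape[0]
    cluster_consensus = {}
    for c in clusters:
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            warnings.warn(f"singleton cluster {c}: cluster consensus undefined")
            cluster_consensus[int(c)] = float("nan")
            continue
        sub = M[np.ix_(idx, idx)]
        cluster_consensus[int(c)] = float(sub[np.triu_indices(idx.size, k=1)].mean())
    item_consensus = np.zeros((n, len(clusters)))
    for ci, c in enumerate(clusters):
        idx = labels == c
        for i in range(n):
            mask = idx.copy()
            mask[i] = False
            item_consensus[i, ci] = M[i, mask].mean() if mask.any() else float("nan")
    return cluster_consensus, item_consensus


@dataclass
class ConsensusResult:
    """Everything the consensus run produced, per candidate k."""

    k_values: tuple
    consensus_matrices: dict  # k -> (n, n) array
    assignments: dict  # k -> labels 1..k
    cdfs: dict  # k -> CDF on CDF_GRID
    areas: dict  # k -> A(k)
    delta_areas: dict  # k -> Delta(k)
    selected_k: int
    cluster_consensus: dict  # per selected k
    item_consensus: np.ndarray
    n_resamples: int
    subsample_fraction: float
    tau: float
    seed: int | None
    never_cosampled_fraction: float = 0.0
    cdf_grid: np.ndarray = field(default_factory=lambda: CDF_GRID.copy())

    @property
    def assignment(self):
        return self.assignments[self.selected_k]

    def summary(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "areas": {str(k): self.areas[k] for k in self.k_values},
            "delta_areas": {str(k): self.delta_areas[k] for k in self.k_values},
            "selected_k": int(self.selected_k),
            "selection_rule": {
                "method": "delta_area",
                "tau": self.tau,
                "description": "largest Delta(k) over k>=3 if it exceeds tau, else 2; "
                               "ties to the smaller k",
            },
            "cluster_consensus": {str(c): v for c, v in self.cluster_consensus.items()},
            "n_resamples": int(self.n_resamples),
            "subsample_fraction": float(self.subsample_fraction),
            "never_cosampled_fraction": float(self.never_cosampled_fraction),
            "seed": self.seed,
        }


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """Consensus hierarchical clustering over item resamples.

    Parameters
    ----------
    k_values : candidate cluster counts, consecutive from 2 (default 2..5).
    n_resamples : number of subsampling repeats (default 100).
    subsample_fraction : fraction of items drawn without replacement per
        resample (default 0.8).
    linkage : {'average', 'complete', 'ward'} for both the inner clusterings
        and the final cut of the consensus matrix.
    distance : {'euclidean', 'pearson'} on the profile rows.
    tau : floor the best Delta(k), k >= 3, must exceed to prefer it over 2.
    random_state : seed for the resampling stream.

    Attributes
    ----------
    result_ : ConsensusResult with matrices, CDFs, areas, deltas, metrics.
    labels_ : final assignment at ``selected_k_`` (labels 1..k).
    selected_k_ : the delta-area choice of k.
    """

    def __init__(self, k_values=(2, 3, 4, 5), n_resamples=100,
                 subsample_fraction=0.8, linkage="average",
                 distance="euclidean", tau=0.1, random_state=None):
        self.k_values = k_values
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.linkage = linkage
        self.distance = distance
        self.tau = tau
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k_values = tuple(int(k) for k in np.atleast_1d(self.k_values))
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be at least 2")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        m = int(np.ceil(self.subsample_fraction * n))
        if max(k_values) >= m:
            raise ValueError(
                f"max k ({max(k_values)}) must be smaller than the subsample size ({m})"
            )
        rng = np.random.default_rng(self.random_state)
        D = _profile_distances(X, self.distance)

        cosampled = np.zeros((n, n))
        coclustered = {k: np.zeros((n, n)) for k in k_values}
        for _ in range(self.n_resamples):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = D[np.ix_(idx, idx)]
            merges = agglomerate(sub, self.linkage)
            cosampled[np.ix_(idx, idx)] += 1.0
            for k in k_values:
                labels = cut_merges(merges, m, k)
                same = labels[:, None] == labels[None, :]
                coclustered[k][np.ix_(idx, idx)] += same

        never = cosampled == 0
        np.fill_diagonal(never, False)
        never_frac = float(never.sum() / (n * (n - 1))) if n > 1 else 0.0
        if never_frac > 0:
            warnings.warn(
                f"{never.sum() // 2} item pairs were never co-sampled; their "
                "consensus is reported as 0"
                + (" (more than 1% of pairs: increase n_resamples or the "
                   "subsample fraction)" if never_frac > 0.01 else "")
            )

        matrices, assignments, cdfs = {}, {}, {}
        with np.errstate(invalid="ignore", divide="ignore"):
            for k in k_values:
                M = np.where(cosampled > 0, coclustered[k] / np.maximum(cosampled, 1), 0.0)
                M = (M + M.T) / 2.0
                np.fill_diagonal(M, 1.0)
                matrices[k] = M
                assignments[k] = hierarchical_cluster(1.0 - M, self.linkage, k)
                cdfs[k] = consensus_cdf(M)
        areas, deltas = delta_area(cdfs)
        selected = select_k(deltas, self.tau)
        cc, ic = stability_metrics(matrices[selected], assignments[selected])

        self.result_ = ConsensusResult(
            k_values=k_values,
            consensus_matrices=matrices,
            assignments=assignments,
            cdfs=cdfs,
            areas=areas,
            delta_areas=deltas,
            selected_k=selected,
            cluster_consensus=cc,
            item_consensus=ic,
            n_resamples=int(self.n_resamples),
            subsample_fraction=float(self.subsample_fraction),
            tau=float(self.tau),
            seed=self.random_state,
            never_cosampled_fraction=never_frac,
        )
        self.labels_ = assignments[selected]
        self.selected_k_ = selected
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cluster(profiles, k_values=(2, 3, 4, 5), n_resamples=100,
                      subsample_fraction=0.8, linkage="average",
                      distance="euclidean", tau=0.1, seed=None) -> ConsensusResult:
    """Functional wrapper around :class:`ConsensusClustering`."""
    X = profiles.to_numpy() if hasattr(profiles, "to_numpy") else np.asarray(profiles)
    est = ConsensusClustering(
        k_values=k_values, n_resamples=n_resamples,
        subsample_fraction=subsample_fraction, linkage=linkage,
        distance=distance, tau=tau, random_state=seed,
    )
    est.fit(X)
    return est.result_
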