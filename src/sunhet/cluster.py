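"""Unsupervised classifiers for heterotic-group discovery.

Three algorithms are implemented here from first principles:

* **Ward.D2 agglomerative clustering** — Lance–Williams recurrence on
  squared Euclidean distances,

      D²(i∪j, k) = [(n_i+n_k) D²(i,k) + (n_j+n_k) D²(j,k) − n_k D²(i,j)]
                   / (n_i + n_j + n_k),

  with merge heights reported on the distance scale (√D²), so the merge of
  two singletons sits exactly at their Euclidean distance.
* **Lloyd k-means** with k-means++ seeding and best-of-``n_init`` restarts.
* **hkmeans** — the hybrid classifier: a Ward.D2 cut provides the initial
  centroids for a single deterministic Lloyd refinement.

Partition-quality metrics (purity against known line types, the
Hubert–Arabie adjusted Rand index) quantify each algorithm's resolution
power.  All functions are pure in (matrix, parameters, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .panel import ValidationError

logger = logging.getLogger(__name__)

MAX_LLOYD_ITER = 300


# ---------------------------------------------------------------------------
# distances


def pairwise_euclidean(M) -> np.ndarray:
    """Symmetric n × n Euclidean distance matrix between rows of ``M``."""
    M = _as_matrix(M)
    return squareform(pdist(M, metric="euclidean"))


def _as_matrix(M) -> np.ndarray:
    if hasattr(M, "values") and isinstance(getattr(M, "values"), pd.DataFrame):
        M = M.values  # FeatureMatrix
    if isinstance(M, pd.DataFrame):
        M = M.to_numpy()
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    if not np.isfinite(M).all():
        raise ValidationError("matrix must be finite")
    return M


# ---------------------------------------------------------------------------
# Ward.D2 agglomeration


@dataclass(frozen=True)
class Dendrogram:
    """Full merge history of an agglomerative clustering.

    ``merges`` is an (n−1) × 4 array in the usual linkage layout: columns are
    (left id, right id, height, merged size), where ids 0..n−1 are leaves and
    id n+i is the cluster created by merge i.
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def __post_init__(self) -> None:
        n = self.n_leaves
        if self.merges.shape != (n - 1, 4):
            raise ValidationError("merge table must have n-1 rows and 4 columns")
        if (self.merges[:, 2] < -1e-12).any():
            raise ValidationError("merge heights must be non-negative")
        if int(self.merges[-1, 3]) != n:
            raise ValidationError("root member count must equal n")


def ward_d2_linkage(D, leaf_ids=None) -> Dendrogram:
    """Agglomerate a distance matrix with the Ward.D2 criterion.

    At each step the globally closest pair (smallest current D²) is merged;
    ties are broken toward the smallest (left, right) cluster-id pair, which
    makes the procedure deterministic.  Height inversions — impossible for
    Euclidean input but conceivable for arbitrary dissimilarities — are
    reported as warnings, not errors.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if n < 2:
        raise ValidationError("need at least two points")
    if leaf_ids is None:
        leaf_ids = tuple(str(i) for i in range(n))
    leaf_ids = tuple(leaf_ids)

    d2 = D.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    size = {i: 1 for i in range(n)}
    # slot -> current cluster id occupying that row/column of d2
    slot_id = list(range(n))
    active = [True] * n
    merges = np.zeros((n - 1, 4))
    prev_height = 0.0

    for step in range(n - 1):
        best = (np.inf, None, None)
        for a in range(n):
            if not active[a]:
                continue
            for b in range(a + 1, n):
                if not active[b]:
                    continue
                v = d2[a, b]
                ia, ib = sorted((slot_id[a], slot_id[b]))
                if v < best[0] - 1e-15 or (
                    abs(v - best[0]) <= 1e-15
                    and best[1] is not None
                    and (ia, ib) < (min(slot_id[best[1]], slot_id[best[2]]),
                                    max(slot_id[best[1]], slot_id[best[2]]))
                ):
                    best = (v, a, b)
        d2min, a, b = best
        ia, ib = sorted((slot_id[a], slot_id[b]))
        height = float(np.sqrt(max(d2min, 0.0)))
        if height < prev_height - 1e-9:
            warnings.warn(
                f"height inversion at merge {step}: {height:.6g} < {prev_height:.6g}",
                RuntimeWarning,
            )
        prev_height = max(prev_height, height)
        ni, nj = size[slot_id[a]], size[slot_id[b]]
        new_id = n + step
        merges[step] = (ia, ib, height, ni + nj)

        # Lance-Williams update into slot a; retire slot b
        for c in range(n):
            if not active[c] or c in (a, b):
                continue
            nk = size[slot_id[c]]
            d2[a, c] = d2[c, a] = (
                (ni + nk) * d2[a, c] + (nj + nk) * d2[b, c] - nk * d2min
            ) / (ni + nj + nk)
        active[b] = False
        size[new_id] = ni + nj
        slot_id[a] = new_id
        d2[b, :] = d2[:, b] = np.inf

    return Dendrogram(merges=merges, leaf_ids=leaf_ids)


def _first_leaf(dend: Dendrogram) -> np.ndarray:
    """Smallest-index leaf under each node (leaves then internal nodes)."""
    n = dend.n_leaves
    first = np.arange(2 * n - 1)
    for i, (a, b, _, _) in enumerate(dend.merges):
        first[n + i] = min(first[int(a)], first[int(b)])
    return first


def cut_tree(
    dend: Dendrogram, k: int | None = None, height: float | None = None
) -> np.ndarray:
    """Cut a dendrogram into flat clusters.

    Exactly one of ``k`` (keep the k−1 highest merges out) or ``height``
    (drop merges above the threshold) must be given.  Cluster labels are
    1-based, numbered by first-leaf order so the genotype listed first in the
    panel always sits in cluster 1.
    """
    if (k is None) == (height is None):
        raise ValidationError("specify exactly one of k or height")
    n = dend.n_leaves
    if k is not None:
        if not 1 <= k <= n:
            raise ValidationError(f"k must be in [1, {n}], got {k}")
        order = np.argsort(dend.merges[:, 2], kind="stable")
        keep = set(order[: n - k].tolist())
    else:
        if height < 0:
            raise ValidationError("height must be non-negative")
        keep = {i for i in range(n - 1) if dend.merges[i, 2] <= height}

    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    first = _first_leaf(dend)
    for i in sorted(keep):
        a, b = int(dend.merges[i, 0]), int(dend.merges[i, 1])
        ra, rb = find(first[a]), find(first[b])
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    labels = np.zeros(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen) + 1
        labels[leaf] = seen[root]
    return labels


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Serialize the merge history as a Newick string.

    Branch lengths are height differences between a node and its parent, so
    the root-to-leaf path length of every leaf equals the root merge height.
    """
    n = dend.n_leaves
    heights = np.concatenate([np.zeros(n), dend.merges[:, 2]])

    def node(i: int, parent_h: float) -> str:
        bl = max(parent_h - heights[i], 0.0)
        if i < n:
            name = str(dend.leaf_ids[i]).replace(" ", "_")
            return f"{name}:{bl:.10g}"
        a, b, h, _ = dend.merges[i - n]
        return f"({node(int(a), h)},{node(int(b), h)}):{bl:.10g}"

    root = 2 * n - 2
    h = heights[root]
    a, b, _, _ = dend.merges[-1]
    return f"({node(int(a), h)},{node(int(b), h)});"


def dendrogram_to_frame(dend: Dendrogram) -> pd.DataFrame:
    """Merge table as a tidy DataFrame (left, right, height, size)."""
    return pd.DataFrame(
        dend.merges, columns=["left", "right", "height", "size"]
    ).astype({"left": int, "right": int, "size": int})


# ---------------------------------------------------------------------------
# k-means


@dataclass(frozen=True)
class KMeansResult:
    """Labels (1..k), centers, within-cluster sum of squares and run metadata."""

    labels: np.ndarray
    centers: np.ndarray
    wss: float
    iterations: int
    seed: int | None

    def __post_init__(self) -> None:
        k = self.centers.shape[0]
        if len(np.unique(self.labels)) != k:
            raise ValidationError("every cluster must be non-empty")


def _kmeanspp_init(M: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = M.shape[0]
    centers = np.empty((k, M.shape[1]))
    centers[0] = M[rng.integers(n)]
    closest = ((M - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = closest.sum()
        if total <= 0:
            centers[j] = M[rng.integers(n)]
        else:
            centers[j] = M[rng.choice(n, p=closest / total)]
        closest = np.minimum(closest, ((M - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(M: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = ((M[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1), d2


def _lloyd_run(
    M: np.ndarray, centers: np.ndarray, max_iter: int = MAX_LLOYD_ITER
) -> tuple[np.ndarray, np.ndarray, float, int]:
    k = centers.shape[0]
    labels = np.full(M.shape[0], -1)
    it = 0
    for it in range(1, max_iter + 1):
        new_labels, d2 = _assign(M, centers)
        # empty-cluster repair: reseed at the point farthest from its center
        for j in range(k):
            if not (new_labels == j).any():
                resid = d2[np.arange(len(new_labels)), new_labels]
                far = int(np.argmax(resid))
                logger.info("reseeding empty cluster %d at point %d", j, far)
                centers[j] = M[far]
                new_labels, d2 = _assign(M, centers)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            centers[j] = M[labels == j].mean(axis=0)
    wss = float(((M - centers[labels]) ** 2).sum())
    return labels, centers, wss, it


def lloyd_kmeans(M, k: int, seed: int = 0, n_init: int = 10) -> KMeansResult:
    """Best-of-``n_init`` Lloyd runs with k-means++ initialization."""
    M = _as_matrix(M)
    n = M.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    if n_init < 1:
        raise ValidationError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(n_init):
        centers = _kmeanspp_init(M, k, rng)
        labels, centers, wss, it = _lloyd_run(M, centers.copy())
        if best is None or wss < best.wss:
            best = KMeansResult(labels=labels + 1, centers=centers,
                                wss=wss, iterations=it, seed=seed)
    return best


def hybrid_hkmeans(M, k: int) -> KMeansResult:
    """Hierarchical-then-k-means hybrid classifier (deterministic).

    The Ward.D2 tree is cut at ``k``; the cut's cluster centroids seed one
    Lloyd refinement, which can only lower the within-cluster sum of squares.
    """
    M = _as_matrix(M)
    dend = ward_d2_linkage(pairwise_euclidean(M))
    init_labels = cut_tree(dend, k=k) - 1
    centers = np.vstack([M[init_labels == j].mean(axis=0) for j in range(k)])
    labels, centers, wss, it = _lloyd_run(M, centers)
    return KMeansResult(labels=labels + 1, centers=centers, wss=wss,
                        iterations=it, seed=None)


def within_cluster_ss(M, labels) -> float:
    """WSS of an arbitrary partition (centroids recomputed from the data)."""
    M = _as_matrix(M)
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        pts = M[labels == lab]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# partition quality


def cluster_purity(labels, classes) -> tuple[float, pd.DataFrame]:
    """Purity of a clustering against known classes.

    purity = (1/n) Σ_clusters max_class |cluster ∩ class|.  Also returns a
    per-cluster table of the majority class and its within-cluster fraction.
    """
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    if labels.size == 0 or labels.size != classes.size:
        raise ValidationError("labels and classes must be equal-length, non-empty")
    ct = pd.crosstab(pd.Series(labels, name="cluster"),
                     pd.Series(classes, name="class"))
    majority = ct.idxmax(axis=1)
    counts = ct.max(axis=1)
    sizes = ct.sum(axis=1)
    table = pd.DataFrame({
        "size": sizes,
        "majority_class": majority,
        "majority_fraction": counts / sizes,
    })
    return float(counts.sum() / labels.size), table


def adjusted_rand(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.size != b.size:
        raise ValidationError("partitions must be equal-length and non-empty")
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    n2 = comb2(a.size)
    expected = sum_a * sum_b / n2
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions trivial (all-singletons or one cluster)
    return float((sum_ij - expected) / (max_index - expected))
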