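"""Neuron clustering by task-conditioned firing rates, and cluster lesioning.

The data matrix ``K [N, n_tasks * n_trials]`` holds each neuron's mean rate
per (task, trial), normalised to the maximum entry.  k-means (Lloyd, best of
several restarts) partitions the neurons by minimising the within-cluster
quadratic deviation; Ward's agglomerative method yields dendrograms over
neurons and over tasks, with merge heights expressed as the increase in the
total within-cluster sum of squares,

    R(A, B) = sum_{i in A+B} (f_i - mu_AB)^2
              - sum_{i in A} (f_i - mu_A)^2 - sum_{i in B} (f_i - mu_B)^2.

Lesioning a cluster zeroes the outgoing recurrent and readout weights of its
neurons (with ``I_rec_j = sum_k w_rec[j,k] z_k``, neuron c's outgoing
recurrent weights are column c of ``W_rec``); isolation keeps only the
cluster's readout columns active and cuts recurrent links into the cluster
from all other neurons.  Both operate on copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .network import NetworkWeights


# ---------------------------------------------------------------------------
# Rate table
# ---------------------------------------------------------------------------


@dataclass
class RateTable:
    """Normalised neuron x (task, trial) mean-rate matrix."""

    k_matrix: np.ndarray          # [N, n_cols], entries in [0, 1]
    normalization: float          # the max raw entry divided out
    column_tasks: list[str]       # task label per column

    @classmethod
    def from_rates(cls, rates_hz: np.ndarray,
                   column_tasks: Sequence[str]) -> "RateTable":
        rates_hz = np.asarray(rates_hz, dtype=float)
        peak = float(rates_hz.max())
        norm = peak if peak > 0 else 1.0
        return cls(rates_hz / norm, norm, list(column_tasks))

    @property
    def n(self) -> int:
        return self.k_matrix.shape[0]

    def task_profile(self) -> tuple[np.ndarray, list[str]]:
        """Rates averaged over trials within each task: ``[N, n_tasks]``."""
        tasks = list(dict.fromkeys(self.column_tasks))
        cols = np.array(self.column_tasks)
        prof = np.column_stack([
            self.k_matrix[:, cols == t].mean(axis=1) for t in tasks])
        return prof, tasks


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


@dataclass
class ClusterPartition:
    """Neuron labels, centroids and the quadratic objective J(C)."""

    labels: np.ndarray      # [N] int
    centroids: np.ndarray   # [k, n_cols]
    objective: float

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def members(self, cluster: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == cluster)
        if idx.size == 0 and cluster not in self.labels:
            raise KeyError(f"cluster {cluster} not present in partition")
        return idx


def kmeans_cluster(table: RateTable, k: int, rng: np.random.Generator,
                   n_restarts: int = 10) -> ClusterPartition:
    """Lloyd's algorithm to convergence; best of ``n_restarts`` by J.

    Empty clusters are re-seeded internally (scikit-learn's policy of
    assigning the points farthest from their centroids).
    """
    if not 1 <= k <= table.n:
        raise ValueError(f"k must be in [1, {table.n}]")
    seed = int(rng.integers(2 ** 31 - 1))
    km = KMeans(n_clusters=k, n_init=n_restarts, algorithm="lloyd",
                random_state=seed)
    labels = km.fit_predict(table.k_matrix)
    return ClusterPartition(labels, km.cluster_centers_, float(km.inertia_))


def choose_k(table: RateTable, rng: np.random.Generator,
             k_range: tuple[int, int] = (2, 20),
             n_restarts: int = 10) -> tuple[int, dict[int, float]]:
    """Cluster count by maximum silhouette over ``k_range`` (inclusive)."""
    lo, hi = k_range
    hi = min(hi, table.n - 1)
    scores: dict[int, float] = {}
    for k in range(lo, hi + 1):
        part = kmeans_cluster(table, k, rng, n_restarts)
        if len(np.unique(part.labels)) < 2:
            continue
        scores[k] = float(silhouette_score(table.k_matrix, part.labels))
    if not scores:
        raise ValueError("no valid k in range")
    best = max(scores, key=scores.get)
    return best, scores


# ---------------------------------------------------------------------------
# Ward hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Linkage:
    """Dendrogram as a merge sequence.

    ``merges[m] = (i, j, R, size)``: at step m clusters i and j (scipy
    convention: original items 0..n-1, merged clusters n+m) join with Ward
    distance R (the within-cluster sum-of-squares increase) into a cluster
    of ``size`` leaves.  ``scipy_linkage`` keeps the raw scipy matrix whose
    heights h relate to R by ``R = h**2 / 2``.
    """

    merges: list[tuple[int, int, float, int]]
    scipy_linkage: np.ndarray

    def to_nested_lists(self):
        """Dendrogram as nested lists of leaf indices (JSON-friendly)."""
        n = len(self.merges) + 1
        nodes: dict[int, object] = {i: i for i in range(n)}
        for m, (i, j, _, _) in enumerate(self.merges):
            nodes[n + m] = [nodes.pop(int(i)), nodes.pop(int(j))]
        (root,) = nodes.values()
        return root


def ward_linkage(data: np.ndarray | RateTable, axis: str = "neurons") -> Linkage:
    """Ward agglomeration over neurons (rows) or tasks (columns).

    For ``axis="tasks"`` the columns are first averaged within task so each
    task contributes one point, giving the task dendrogram.
    """
    if isinstance(data, RateTable):
        if axis == "tasks":
            prof, _ = data.task_profile()
            X = prof.T
        else:
            X = data.k_matrix
    else:
        X = np.asarray(data, dtype=float)
        if axis == "tasks":
            X = X.T
    if X.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    L = _scipy_linkage(X, method="ward")
    merges = [(int(r[0]), int(r[1]), float(r[2]) ** 2 / 2.0, int(r[3]))
              for r in L]
    return Linkage(merges, L)


# ---------------------------------------------------------------------------
# Lesioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """Which cluster to silence (``lesion``) or keep alone (``isolate``)."""

    cluster: int
    mode: str = "lesion"

    def __post_init__(self):
        if self.mode not in ("lesion", "isolate"):
            raise ValueError(f"mode must be 'lesion' or 'isolate', got {self.mode!r}")


def lesion(w: NetworkWeights, part: ClusterPartition,
           spec: LesionSpec) -> NetworkWeights:
    """Return a modified copy of the weights per the lesion specification.

    ``lesion``: zero the cluster neurons' outgoing columns of ``W_rec`` and
    ``W_out`` — the cluster still receives input but no longer influences
    anyone.  ``isolate``: only the cluster's ``W_out`` columns stay active,
    and recurrent links into the cluster from non-cluster neurons are cut
    (external input via ``W_in`` is left intact).
    """
    if spec.cluster not in part.labels:
        raise KeyError(f"cluster {spec.cluster} not present in partition")
    idx = part.members(spec.cluster)
    out = w.copy()
    if spec.mode == "lesion":
        out.w_rec[:, idx] = 0.0
        out.w_out[:, idx] = 0.0
    else:
        others = np.setdiff1d(np.arange(w.n), idx)
        out.w_out[:, others] = 0.0
        out.w_rec[np.ix_(idx, others)] = 0.0
    return out


def lesion_screen(w: NetworkWeights, part: ClusterPartition, evaluate_fn,
                  modes: Sequence[str] = ("lesion", "isolate")):
    """Per-(cluster, task) accuracy for each mode.

    ``evaluate_fn(weights)`` must return a mapping ``task name -> accuracy``
    (e.g. a closure over :func:`spikecog.evaluation.evaluate_network` with a
    fixed trial budget — 200 test trials per cell in the reference
    protocol).  Returns ``{mode: DataFrame [n_clusters x n_tasks]}``.
    """
    import pandas as pd

    clusters = sorted(np.unique(part.labels))
    result = {}
    for mode in modes:
        rows = []
        for c in clusters:
            wl = lesion(w, part, LesionSpec(int(c), mode))
            rows.append(evaluate_fn(wl))
        result[mode] = pd.DataFrame(rows, index=[f"cluster_{c}" for c in clusters])
    return result
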