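"""Conformational clustering of snapshots by chromophore-ring RMSD.

Protocol: every frame is rigidly fitted to one reference (the minimized
start) on the backbone selection; pairwise RMSDs over the ring heavy
atoms are then taken in that common frame, without per-pair
re-superposition.  Clustering is hierarchical agglomerative with the
unweighted average-linkage (UPGMA) merge rule; labels are reported in
descending cluster-size order, the convention used for cluster tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .ensemble_io import Trajectory
from .structure import fit_trajectory, kabsch_fit

__all__ = [
    "ClusterAssignment",
    "pairwise_rmsd_matrix",
    "average_linkage",
    "cluster_representatives",
]


@dataclass
class ClusterAssignment:
    """Per-frame labels (0-based, ordered by descending cluster size),
    per-cluster medoid frames, and the linkage merge heights."""

    labels: np.ndarray
    representatives: np.ndarray
    linkage_height: np.ndarray
    linkage_matrix: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def pairwise_rmsd_matrix(traj: Trajectory, ref_frame, fit_selection,
                         eval_selection, pairwise_refit: bool = False) -> np.ndarray:
    """Condensed pairwise RMSD matrix over the eval selection.

    Default: single-reference protocol (fit once to ``ref_frame`` on
    ``fit_selection``, compare eval coordinates directly).  With
    ``pairwise_refit=True`` each pair is optimally superposed instead
    (O(n^2) Kabsch fits; substantially slower).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    fit_sel = np.asarray(fit_selection, dtype=int)
    eval_sel = np.asarray(eval_selection, dtype=int)
    if fit_sel.size == 0 or eval_sel.size == 0:
        raise ValueError("empty selection")
    fitted = fit_trajectory(traj, ref_frame, fit_sel)[:, eval_sel]
    if pairwise_refit:
        n = traj.n_frames
        out = np.zeros(n * (n - 1) // 2)
        k = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                _, d = kabsch_fit(fitted[j], fitted[i])
                out[k] = d
                k += 1
        return out
    # In a common frame, RMSD_ij = ||x_i - x_j||_F / sqrt(m)
    flat = fitted.reshape(traj.n_frames, -1)
    return pdist(flat) / np.sqrt(eval_sel.size)


def average_linkage(distances: np.ndarray, k: int | None = None,
                    height: float | None = None) -> ClusterAssignment:
    """Average-linkage (UPGMA) agglomerative clustering.

    Cut either at a fixed cluster count ``k`` or at a merge-height
    cutoff ``height`` (exactly one must be given).  Cluster ids are
    re-ordered by descending size; equal sizes break by the smallest
    member frame index, so the labeling is deterministic.
    """
    distances = np.asarray(distances, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * distances.size)) / 2))
    if n * (n - 1) // 2 != distances.size:
        raise ValueError("not a condensed distance matrix")
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    z = linkage(distances, method="average")
    if k is not None:
        raw = fcluster(z, t=k, criterion="maxclust")
    else:
        if height < 0:
            raise ValueError("height cutoff must be >= 0")
        raw = fcluster(z, t=height, criterion="distance")
    labels = _relabel_by_size(raw - 1)
    reps = cluster_representatives(labels, distances)
    return ClusterAssignment(labels=labels, representatives=reps,
                             linkage_height=z[:, 2].copy(), linkage_matrix=z)


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    first_member = np.array([np.argmax(raw == i) for i in ids])
    order = np.lexsort((first_member, -counts))
    remap = np.empty(ids.max() + 1, dtype=int)
    for new, old_pos in enumerate(order):
        remap[ids[old_pos]] = new
    return remap[raw]


def cluster_representatives(labels: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Medoid frame of each cluster: the member minimizing summed
    within-cluster distance; ties break to the lowest frame index."""
    labels = np.asarray(labels, dtype=int)
    full = squareform(np.asarray(distances, dtype=float))
    n_clusters = labels.max() + 1
    reps = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        sums = full[np.ix_(members, members)].sum(axis=1)
        reps[c] = members[np.argmin(sums)]  # argmin: first = lowest index
    return reps
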