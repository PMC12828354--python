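"""Data-driven clustering of single-voxel autocorrelation vectors.

Pairwise Euclidean distances between per-voxel lag vectors are turned into a
similarity matrix (normalized by the maximum distance and subtracted from 1,
so similarities span [0, 1]), which defines a complete weighted graph.
Communities are found by modularity optimization (multilevel Louvain), which
estimates the number of clusters from the data rather than requiring it in
advance. Clusters are then given functional role labels by ranking their
mean lag-1 autocorrelation: the highest-autocorrelation cluster is the
anterior-medial role, the lowest the posterior-lateral role, with an
intermediate role in between — the ordering the hippocampal long-axis
gradient produces.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .autocorr import AutocorrMap
from .io import RoiMask

__all__ = [
    "SimilarityMatrix",
    "ClusterMap",
    "similarity_matrix",
    "modularity_clusters",
    "label_clusters_by_autocorr",
    "group_similarity",
    "cluster_sizes",
    "ROLE_ANTERIOR_MEDIAL",
    "ROLE_INTERMEDIATE",
    "ROLE_POSTERIOR_LATERAL",
]

ROLE_ANTERIOR_MEDIAL = "anterior-medial"
ROLE_INTERMEDIATE = "intermediate"
ROLE_POSTERIOR_LATERAL = "posterior-lateral"

UNASSIGNED = -1  # label for voxels excluded from clustering (degenerate)


@dataclass
class SimilarityMatrix:
    """Symmetric voxel-pair similarity in [0, 1], diagonal = 1."""

    values: np.ndarray
    mask_ref: RoiMask | None = None
    source: str = "individual"
    index: np.ndarray | None = None  # mask-order positions of the rows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if self.index is None:
            self.index = np.arange(n)
        else:
            self.index = np.asarray(self.index, dtype=int)
            if self.index.shape[0] != n:
                raise ValueError("index length must match matrix size")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterMap:
    """Per-voxel integer cluster labels plus a rank-based role ordering.

    ``labels`` follows the mask voxel ordering; degenerate voxels carry -1.
    ``role_order`` maps each label to its role once
    :func:`label_clusters_by_autocorr` has run.
    """

    labels: np.ndarray
    n_clusters: int
    modularity_q: float
    seed: int
    mask_ref: RoiMask | None = None
    role_order: dict[int, str] = field(default_factory=dict)
    role_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.n_clusters < 1:
            raise ValueError("a cluster map needs at least one cluster")

    def role_voxels(self, role: str) -> np.ndarray:
        """Mask-order positions of the voxels carrying ``role``."""
        if not self.role_order:
            raise ValueError("cluster map has no role labels yet")
        members = [lab for lab, r in self.role_order.items() if r == role]
        if not members:
            return np.array([], dtype=int)
        return np.flatnonzero(np.isin(self.labels, members))

    @property
    def roles(self) -> list[str]:
        """Roles in rank order (highest mean lag-1 autocorrelation first)."""
        return list(self.role_means.keys())


def similarity_matrix(acmap: AutocorrMap) -> SimilarityMatrix:
    """Distance -> similarity transform of the lag vectors.

    D is the Euclidean distance between autocorrelation vectors; the matrix
    is normalized by its maximum and subtracted from 1, so the most distant
    voxel pair has similarity 0 and identical vectors similarity 1. The
    normalizing maximum is per-map (per individual and hemisphere).
    """
    valid_idx = np.flatnonzero(acmap.valid)
    if valid_idx.size < 2:
        raise ValueError("need at least 2 non-degenerate voxels")
    vecs = acmap.values[valid_idx]
    diff = vecs[:, None, :] - vecs[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    dmax = D.max()
    if dmax == 0:
        warnings.warn(
            "all autocorrelation vectors identical; similarity degenerates to all-ones",
            stacklevel=2,
        )
        S = np.ones_like(D)
    else:
        S = 1.0 - D / dmax
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(values=S, mask_ref=acmap.mask_ref, index=valid_idx)


def modularity_clusters(
    sim: SimilarityMatrix,
    seed: int = 0,
    n_restarts: int = 20,
    resolution: float = 1.0,
) -> ClusterMap:
    """Louvain modularity optimization on the complete similarity graph.

    Self-weights are zeroed before graph construction. The optimization is
    order-dependent, so it is restarted ``n_restarts`` times from seeded RNG
    states and the partition with the highest modularity is kept; identical
    seed and input give an identical partition. The trivial one-community
    partition (Q = 0) is the floor, so the returned modularity is >= 0.
    """
    W = sim.values.copy()
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    off = W[~np.eye(n, dtype=bool)]
    if n < 2 or np.allclose(off, off[0]):
        warnings.warn("degenerate similarity; returning a single cluster", stacklevel=2)
        return ClusterMap(
            labels=_expand_labels(np.zeros(n, dtype=int), sim),
            n_clusters=1,
            modularity_q=0.0,
            seed=seed,
            mask_ref=sim.mask_ref,
        )

    g = ig.Graph.Weighted_Adjacency(W, mode="undirected", attr="weight", loops=False)
    weights = g.es["weight"]
    rng = random.Random(seed)
    best_q, best_membership = -np.inf, None
    for _ in range(n_restarts):
        state = random.getstate()
        random.seed(rng.randrange(2**31))  # igraph draws from the stdlib RNG
        try:
            part = g.community_multilevel(weights=weights, resolution=resolution)
        finally:
            random.setstate(state)
        q = g.modularity(part.membership, weights=weights)
        if q > best_q:
            best_q, best_membership = q, np.asarray(part.membership)
    if best_q < 0:  # never worse than the trivial one-community partition
        best_membership = np.zeros(n, dtype=int)
        best_q = 0.0
    labels = _canonical_labels(best_membership)
    return ClusterMap(
        labels=_expand_labels(labels, sim),
        n_clusters=int(labels.max()) + 1,
        modularity_q=float(best_q),
        seed=seed,
        mask_ref=sim.mask_ref,
    )


def label_clusters_by_autocorr(cm: ClusterMap, acmap: AutocorrMap) -> ClusterMap:
    """Assign functional roles by ranking cluster-mean lag-1 autocorrelation.

    Rank 1 (highest mean) is anterior-medial, the last rank posterior-lateral,
    rank 2 intermediate when three or more clusters exist; additional middle
    ranks are labeled ``extra-<rank>``. Ties are broken by cluster size
    (larger first) and then by lowest original label, so the ordering is
    deterministic.
    """
    lag1 = acmap.lag1
    labs = [lab for lab in np.unique(cm.labels) if lab != UNASSIGNED]
    stats = []
    for lab in labs:
        sel = cm.labels == lab
        stats.append((lab, float(np.nanmean(lag1[sel])), int(sel.sum())))
    stats.sort(key=lambda s: -s[1])
    # means within 1e-12 are ties: larger cluster first, then lowest label
    i = 0
    while i < len(stats):
        j = i + 1
        while j < len(stats) and stats[i][1] - stats[j][1] <= 1e-12:
            j += 1
        stats[i:j] = sorted(stats[i:j], key=lambda s: (-s[2], s[0]))
        i = j
    k = len(stats)
    role_order: dict[int, str] = {}
    role_means: dict[str, float] = {}
    for rank, (lab, mean, _size) in enumerate(stats, start=1):
        role = _role_for_rank(rank, k)
        role_order[lab] = role
        role_means[role] = mean
    return ClusterMap(
        labels=cm.labels,
        n_clusters=cm.n_clusters,
        modularity_q=cm.modularity_q,
        seed=cm.seed,
        mask_ref=cm.mask_ref,
        role_order=role_order,
        role_means=role_means,
    )


def group_similarity(sims: list[SimilarityMatrix], source: str = "group") -> SimilarityMatrix:
    """Group-level similarity: the elementwise mean of individual matrices."""
    if not sims:
        raise ValueError("no similarity matrices to average")
    first = sims[0]
    for s in sims[1:]:
        if s.n_voxels != first.n_voxels or not np.array_equal(s.index, first.index):
            raise ValueError("similarity matrices do not share a mask/ordering")
    mean = np.mean([s.values for s in sims], axis=0)
    return SimilarityMatrix(values=mean, mask_ref=first.mask_ref, source=source, index=first.index)


def cluster_sizes(cm: ClusterMap) -> dict[str, int]:
    """Voxel count per role (or per raw label if roles are not assigned)."""
    if cm.role_order:
        return {role: int(cm.role_voxels(role).size) for role in cm.roles}
    labs, counts = np.unique(cm.labels[cm.labels != UNASSIGNED], return_counts=True)
    return {str(lab): int(c) for lab, c in zip(labs, counts)}


def _role_for_rank(rank: int, k: int) -> str:
    if rank == 1:
        return ROLE_ANTERIOR_MEDIAL
    if rank == k:
        return ROLE_POSTERIOR_LATERAL
    if rank == 2:
        return ROLE_INTERMEDIATE
    return f"extra-{rank}"


def _canonical_labels(membership: np.ndarray) -> np.ndarray:
    """Relabel communities by first occurrence so output is order-stable."""
    mapping: dict[int, int] = {}
    out = np.empty_like(membership)
    for i, m in enumerate(membership):
        if m not in mapping:
            mapping[m] = len(mapping)
        out[i] = mapping[m]
    return out


def _expand_labels(labels: np.ndarray, sim: SimilarityMatrix) -> np.ndarray:
    """Place subset labels back at their mask-order positions (-1 elsewhere)."""
    n_total = sim.index.max() + 1 if sim.index.size else 0
    if sim.mask_ref is not None:
        n_total = sim.mask_ref.n_voxels
    elif sim.index.size == sim.values.shape[0] and np.array_equal(
        sim.index, np.arange(sim.values.shape[0])
    ):
        n_total = sim.values.shape[0]
    full = np.full(int(n_total), UNASSIGNED, dtype=int)
    full[sim.index] = labels
    return full
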