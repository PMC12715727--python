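"""Louvain modularity community detection on weighted undirected graphs.

Greedy local moving plus graph aggregation (Blondel et al. style): each pass
visits nodes in a seed-shuffled order and moves a node to the neighboring
community with the largest modularity gain; once no move helps, communities
are collapsed into super-nodes and the procedure repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from ._utils import rng_from
from .exceptions import InputValidationError, UndefinedStatisticError

__all__ = ["CommunityPartition", "modularity", "louvain", "compare_partitions"]


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity score."""

    assignment: dict
    modularity_q: float
    n_communities: int
    resolution: float
    seed: int
    weight_transform: str = "abs"

    def labels(self, nodes=None) -> np.ndarray:
        keys = list(self.assignment) if nodes is None else list(nodes)
        return np.array([self.assignment[k] for k in keys])


def _as_weight_matrix(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InputValidationError("W must be square")
    if not np.allclose(W, W.T):
        raise InputValidationError("W must be symmetric")
    return W


def modularity(W, partition, resolution: float = 1.0) -> float:
    """Newman modularity Q of a partition on a nonnegative weight matrix.

    Q = (1/2m) * sum_ij [A_ij - resolution * k_i k_j / 2m] * [c_i == c_j].
    """
    A = _as_weight_matrix(W)
    if np.any(A < 0):
        raise InputValidationError("modularity requires nonnegative weights")
    labels = np.asarray(
        [partition[i] for i in range(A.shape[0])]
        if isinstance(partition, dict)
        else partition
    )
    if labels.size != A.shape[0]:
        raise InputValidationError("partition must assign every node")
    two_m = A.sum()
    if two_m == 0:
        raise UndefinedStatisticError("modularity undefined on an edgeless graph")
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((A - resolution * np.outer(k, k) / two_m) * same).sum() / two_m)


def transform_weights(W, weight_transform: str = "abs") -> np.ndarray:
    """Map possibly-signed edge weights onto the nonnegative scale Louvain needs."""
    A = _as_weight_matrix(W).copy()
    np.fill_diagonal(A, 0.0)
    if weight_transform == "abs":
        return np.abs(A)
    if weight_transform == "positive-only":
        return np.clip(A, 0.0, None)
    raise InputValidationError(f"unknown weight transform {weight_transform!r}")


def _one_level(S: np.ndarray, rng, resolution: float):
    """One round of local moving on (possibly aggregated) adjacency S.

    Convention: S[i, i] holds twice the internal weight of super-node i, so
    k = S.sum(axis=1) and 2m = S.sum().
    """
    n = S.shape[0]
    comm = np.arange(n)
    k = S.sum(axis=1)
    two_m = S.sum()
    sigma_tot = k.copy()
    improved_any = False
    while True:
        moved = False
        order = rng.permutation(n)
        for i in order:
            ci = comm[i]
            # link weight from i to each community (excluding the self-loop)
            links = np.zeros(n)
            for j in range(n):
                if j != i and S[i, j] != 0:
                    links[comm[j]] += S[i, j]
            sigma_tot[ci] -= k[i]
            candidates = np.flatnonzero(links != 0)
            best_c, best_gain = ci, links[ci] - resolution * sigma_tot[ci] * k[i] / two_m
            for c in candidates:
                gain = links[c] - resolution * sigma_tot[c] * k[i] / two_m
                if gain > best_gain + 1e-15:
                    best_gain, best_c = gain, c
            sigma_tot[best_c] += k[i]
            if best_c != ci:
                comm[i] = best_c
                moved = True
                improved_any = True
        if not moved:
            break
    return comm, improved_any


def _aggregate(S: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, inverse = np.unique(comm, return_inverse=True)
    nc = labels.size
    M = np.zeros((nc, S.shape[0]))
    M[inverse, np.arange(S.shape[0])] = 1.0
    return M @ S @ M.T, inverse


def louvain(
    W,
    weight_transform: str = "abs",
    resolution: float = 1.0,
    seed: int = 0,
) -> CommunityPartition:
    """Louvain community detection on a (possibly signed) weight matrix.

    Negative edges are mapped to nonnegative weights by ``weight_transform``
    ('abs' by default, 'positive-only' as the alternative). Node visit order
    is shuffled by ``seed``; output is deterministic given (W, settings,
    seed). Isolated nodes end up as singleton communities.
    """
    A = transform_weights(W, weight_transform)
    if A.sum() == 0:
        raise InputValidationError("transformed graph has no edges")
    rng = rng_from(seed)
    node_comm = np.arange(A.shape[0])  # original node -> current super-node
    S = A.copy()
    while True:
        comm, improved = _one_level(S, rng, resolution)
        S, inverse = _aggregate(S, comm)
        node_comm = inverse[node_comm]
        if not improved or S.shape[0] == 1:
            break

    # contiguous ids in order of first appearance
    order = {}
    final = np.empty(A.shape[0], dtype=int)
    for i, c in enumerate(node_comm):
        final[i] = order.setdefault(c, len(order))
    q = modularity(A, final, resolution=resolution)
    return CommunityPartition(
        assignment={i: int(final[i]) for i in range(A.shape[0])},
        modularity_q=q,
        n_communities=int(final.max()) + 1,
        resolution=resolution,
        seed=seed,
        weight_transform=weight_transform,
    )


def _labels_pair(p1, p2):
    if isinstance(p1, CommunityPartition):
        p1 = p1.assignment
    if isinstance(p2, CommunityPartition):
        p2 = p2.assignment
    if isinstance(p1, dict) or isinstance(p2, dict):
        if not (isinstance(p1, dict) and isinstance(p2, dict)):
            raise InputValidationError("partitions must both be dicts or both sequences")
        if set(p1) != set(p2):
            raise InputValidationError("partitions are over different node sets")
        keys = sorted(p1)
        return np.array([p1[k] for k in keys]), np.array([p2[k] for k in keys])
    a, b = np.asarray(p1), np.asarray(p2)
    if a.size != b.size:
        raise InputValidationError("partitions are over different node sets")
    return a, b


def compare_partitions(p1, p2) -> tuple[float, float]:
    """Adjusted Rand index and normalized mutual information of two partitions."""
    a, b = _labels_pair(p1, p2)
    return float(adjusted_rand_score(a, b)), float(normalized_mutual_info_score(a, b))
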