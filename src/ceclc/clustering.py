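"""Hierarchical clustering of traits on correlation distance.

Traits are clustered agglomeratively using the dissimilarity d(j, k) =
1 - r_jk, where r is the estimated trait correlation matrix. Negative
correlations give distances above 1 and are used as-is, so anticorrelated
traits merge last — the linear combinations downstream are meant to pool
positively correlated clusters.

The agglomeration is implemented here (rather than delegated) so the merge
order is fully deterministic: at equal merge heights the pair whose smallest
leaf indices are lexicographically least is merged first. Average linkage
(UPGMA) is the default; complete and single linkage are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LINKAGES = ("average", "complete", "single")


@dataclass
class ClusterTree:
    """Merge sequence over K leaves, scipy-style: leaves are 0..K-1 and the
    cluster created by merge t gets id K + t. Each merge is
    (left_id, right_id, height) with left holding the smaller leaf index."""

    merges: list[tuple[int, int, float]]
    n_leaves: int
    leaf_labels: list[str]
    method: str = "average"

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over K leaves must have exactly K - 1 merges")


@dataclass
class MembershipMatrix:
    """K x L 0/1 matrix B; B[k, l] = 1 iff trait k belongs to cluster l."""

    B: np.ndarray
    L: int

    def __post_init__(self):
        self.B = np.asarray(self.B)
        if self.B.ndim != 2 or self.B.shape[1] != self.L:
            raise ValueError("B must be K x L")
        if not np.all((self.B == 0) | (self.B == 1)):
            raise ValueError("B entries must be 0/1")
        if not np.all(self.B.sum(axis=1) == 1):
            raise ValueError("each trait must belong to exactly one cluster")
        if not np.all(self.B.sum(axis=0) >= 1):
            raise ValueError("each cluster must be non-empty")

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.B, axis=1)


def _check_sigma(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("correlation matrix must be square")
    if sigma.shape[0] == 0:
        raise ValueError("empty correlation matrix")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(sigma), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return sigma


def build_tree(
    sigma_hat: np.ndarray,
    linkage: str = "average",
    leaf_labels: list[str] | None = None,
    check: bool = True,
) -> ClusterTree:
    """Agglomerative clustering of traits with distance 1 - sigma_hat."""
    sigma = _check_sigma(sigma_hat) if check else np.asarray(sigma_hat, dtype=float)
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    k = sigma.shape[0]
    labels = list(leaf_labels) if leaf_labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("leaf_labels length must equal K")
    dist = 1.0 - sigma
    merges = _agglomerate(dist, linkage)
    return ClusterTree(merges=merges, n_leaves=k, leaf_labels=labels, method=linkage)


def _agglomerate(dist: np.ndarray, linkage: str) -> list[tuple[int, int, float]]:
    # Each cluster lives in the slot of its smallest leaf (a merge keeps the
    # left slot), so the row-major argmin over the upper triangle implements
    # the lexicographic tie-break at equal heights. Dead slots are masked
    # with +inf instead of being deleted.
    k = dist.shape[0]
    d = np.where(np.triu(np.ones((k, k), dtype=bool), 1), dist, np.inf)
    ids = list(range(k))
    sizes = np.ones(k)
    merges: list[tuple[int, int, float]] = []
    for t in range(k - 1):
        pos = int(np.argmin(d))
        i, j = divmod(pos, k)
        h = float(d[i, j])
        merges.append((ids[i], ids[j], h))
        # distances of every other live cluster m to i and to j
        di = np.minimum(d[i, :], d[:, i])
        dj = np.minimum(d[j, :], d[:, j])
        if linkage == "average":
            new = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        elif linkage == "complete":
            new = np.maximum(di, dj)
        else:
            new = np.minimum(di, dj)
        new[~np.isfinite(new)] = np.inf
        d[i, i + 1:] = new[i + 1:]
        d[:i, i] = new[:i]
        d[j, :] = np.inf
        d[:, j] = np.inf
        d[i, j] = np.inf
        ids[i] = k + t
        sizes[i] += sizes[j]
    return merges


def cut_labels(tree: ClusterTree, L: int) -> np.ndarray:
    """Length-K integer labels for the partition into L clusters.

    Labels are canonical: numbered by first appearance along the trait order.
    """
    k = tree.n_leaves
    if not 1 <= L <= k:
        raise ValueError(f"L must be in 1..{k}")
    lab = np.arange(k)
    cluster_label = {i: i for i in range(k)}
    for t in range(k - L):
        left, right, _ = tree.merges[t]
        lab[lab == cluster_label[right]] = cluster_label[left]
        cluster_label[k + t] = cluster_label[left]
    return _canonical(lab)


def _canonical(lab: np.ndarray) -> np.ndarray:
    # Renumber labels by first appearance along the trait order.
    mapping: dict[int, int] = {}
    out = np.empty(lab.size, dtype=np.intp)
    for idx, v in enumerate(lab.tolist()):
        out[idx] = mapping.setdefault(v, len(mapping))
    return out


def all_cut_labels(tree: ClusterTree) -> np.ndarray:
    """K x K integer matrix; row L-1 holds the labels of the L-cluster cut."""
    k = tree.n_leaves
    out = np.empty((k, k), dtype=np.intp)
    lab = np.arange(k)
    out[k - 1] = lab
    cluster_label = np.arange(2 * k - 1)
    lab = lab.copy()
    for t, (left, right, _) in enumerate(tree.merges):
        lab[lab == cluster_label[right]] = cluster_label[left]
        cluster_label[k + t] = cluster_label[left]
        out[k - t - 2] = _canonical(lab)
    return out


def membership_from_labels(labels: np.ndarray) -> MembershipMatrix:
    labels = _canonical(np.asarray(labels))
    L = int(labels.max()) + 1
    b = np.zeros((labels.size, L), dtype=np.int8)
    b[np.arange(labels.size), labels] = 1
    return MembershipMatrix(B=b, L=L)


def cut_tree(tree: ClusterTree, L: int) -> MembershipMatrix:
    """Membership matrix obtained by undoing the last L - 1 merges."""
    return membership_from_labels(cut_labels(tree, L))


def all_cuts(sigma_hat: np.ndarray, linkage: str = "average") -> list[MembershipMatrix]:
    """Membership matrices for every cut L = 1..K of one clustering tree."""
    tree = build_tree(sigma_hat, linkage=linkage)
    lab = all_cut_labels(tree)
    return [membership_from_labels(lab[L - 1]) for L in range(1, tree.n_leaves + 1)]


def to_newick(tree: ClusterTree) -> str:
    """Newick serialisation of the dendrogram with merge heights as node labels."""
    k = tree.n_leaves
    nodes: dict[int, str] = {i: tree.leaf_labels[i] for i in range(k)}
    heights: dict[int, float] = {i: 0.0 for i in range(k)}
    for t, (left, right, h) in enumerate(tree.merges):
        bl = max(h - heights[left], 0.0)
        br = max(h - heights[right], 0.0)
        nodes[k + t] = f"({nodes[left]}:{bl:g},{nodes[right]}:{br:g})"
        heights[k + t] = h
    return nodes[2 * k - 2] + ";" if k > 1 else nodes[0] + ";"
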