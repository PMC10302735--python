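"""Co-association machinery and the four graph-based consensus solvers.

A partition's connectivity matrix has 1 where two instances share a cluster;
averaging connectivity matrices over the ensemble gives the consensus
(co-association) matrix CM~ with dispersion diagnostic dCM2.  Four classical
consensus solvers operate on this machinery: CSPA (average-linkage on
1 - CM~), MCLA (meta-clustering of hyperedges), HBGF (bipartite spectral
partitioning) and an approximate HGPA (star-expansion spectral embedding with
balance-constrained local min-cut refinement, labeled "hgpa-approx").  ANMI
scores a candidate consensus against every ensemble member.

All solvers are deterministic given the ensemble, and invariant to member
order and member label permutation (hyperedges are canonically sorted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import svd
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .baseline_ensemble import Partition, PartitionEnsemble
from .motion_io import ValidationError

# ---------------------------------------------------------------------------
# Connectivity / consensus matrices
# ---------------------------------------------------------------------------


@dataclass
class ConsensusMatrix:
    """Averaged co-association matrix over a T-member ensemble.

    Entries lie on the grid {0, 1/T, ..., 1}; ``dispersion`` is the mean
    (over members) total squared deviation of member co-associations from
    the average — zero iff all members induce identical co-associations.
    """

    cm: np.ndarray
    T: int
    dispersion: float

    @property
    def n(self) -> int:
        return self.cm.shape[0]


def connectivity(p: Partition) -> np.ndarray:
    """Binary symmetric n x n matrix: 1 iff two instances share a cluster."""
    labels = p.labels
    return (labels[:, None] == labels[None, :]).astype(float)


def average_consensus(ens: PartitionEnsemble) -> ConsensusMatrix:
    """Elementwise mean of member connectivity matrices, with dispersion."""
    if ens.T < 2:
        raise ValidationError("average_consensus needs >= 2 members")
    mats = [connectivity(p) for p in ens.partitions]
    cm = np.mean(mats, axis=0)
    dispersion = float(np.mean([np.sum((m - cm) ** 2) for m in mats]))
    return ConsensusMatrix(cm=cm, T=ens.T, dispersion=dispersion)


def partition_distance(p1: Partition, p2: Partition) -> int:
    """Count of ordered instance pairs on which the two partitions disagree.

    Equal to the elementwise L1 distance between the connectivity matrices;
    a pseudometric on partitions, invariant to label permutation.
    """
    if p1.n != p2.n:
        raise ValidationError("partitions have different n")
    return int(np.abs(connectivity(p1) - connectivity(p2)).sum())


# ---------------------------------------------------------------------------
# Shared hypergraph helpers
# ---------------------------------------------------------------------------


def hyperedge_matrix(ens: PartitionEnsemble) -> np.ndarray:
    """Binary n x C indicator matrix, one column per member-cluster.

    Columns are sorted canonically (lexicographically as bit vectors), which
    makes every hyperedge-based solver invariant to member order and member
    label permutation.
    """
    cols = []
    for p in ens.partitions:
        for c in range(p.k):
            col = (p.labels == c).astype(float)
            if col.any():
                cols.append(col)
    H = np.column_stack(cols)
    order = np.lexsort(H[::-1])  # lexicographic by column, top row major
    return H[:, order]


def hyperedge_cut(labels: np.ndarray, H: np.ndarray) -> int:
    """Number of hyperedges whose member instances span more than one part."""
    cut = 0
    for j in range(H.shape[1]):
        members = labels[H[:, j] > 0]
        if members.size and np.unique(members).size > 1:
            cut += 1
    return cut


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    remap = {c: i for i, c in enumerate(dict.fromkeys(labels.tolist()))}
    return np.array([remap[c] for c in labels])


def _ensure_k_nonempty(labels: np.ndarray, k: int, affinity: np.ndarray) -> np.ndarray:
    """Repair empty clusters by moving the best-affine instance into them.

    ``affinity[i, c]`` scores instance i for cluster c (higher = better);
    the donor is the instance with the highest affinity for the empty
    cluster among clusters that keep >= 1 member.
    """
    labels = labels.copy()
    for c in range(k):
        if np.any(labels == c):
            continue
        counts = np.bincount(labels, minlength=k)
        movable = counts[labels] > 1
        if not movable.any():
            continue
        cand = np.where(movable)[0]
        donor = cand[np.argmax(affinity[cand, c])]
        labels[donor] = c
    return labels


def _seeded_kmeans(Z: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic k-means on an embedding; returns labels and -distances."""
    km = KMeans(n_clusters=k, n_init=10, random_state=0)
    labels = km.fit_predict(Z)
    return labels, -km.transform(Z)


def _bipartite_spectral(H: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Spectral co-clustering embedding of the instance x hyperedge graph.

    Normalizes the incidence matrix by vertex degrees, takes the k leading
    singular-vector pairs, stacks scaled instance and hyperedge embeddings,
    and jointly k-means-partitions all vertices; returns instance labels and
    the instance affinity (negative k-means distances).
    """
    d1 = H.sum(axis=1)
    d2 = H.sum(axis=0)
    d1s = 1.0 / np.sqrt(np.maximum(d1, 1e-12))
    d2s = 1.0 / np.sqrt(np.maximum(d2, 1e-12))
    An = d1s[:, None] * H * d2s[None, :]
    U, _, Vt = svd(An, full_matrices=False)
    dim = min(k, U.shape[1])
    Zu = d1s[:, None] * U[:, :dim]
    Zv = d2s[:, None] * Vt.T[:, :dim]
    Z = np.vstack([Zu, Zv])
    labels_all, aff_all = _seeded_kmeans(Z, k)
    n = H.shape[0]
    return labels_all[:n], aff_all[:n]


# ---------------------------------------------------------------------------
# CSPA
# ---------------------------------------------------------------------------


def cspa(ens: PartitionEnsemble, k: int) -> Partition:
    """Similarity-partitioning consensus: average-linkage cut of 1 - CM~."""
    cm = average_consensus(ens).cm
    dist = 1.0 - cm
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return Partition(labels=_compact_labels(labels), k=k, method="cspa")


# ---------------------------------------------------------------------------
# MCLA
# ---------------------------------------------------------------------------


def _jaccard(H: np.ndarray) -> np.ndarray:
    inter = H.T @ H
    sizes = H.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def _group_hyperedges(S: np.ndarray, k: int) -> np.ndarray:
    """Spectral partition of the hyperedge similarity graph into k groups."""
    C = S.shape[0]
    if C <= k:
        return np.arange(C)
    d = S.sum(axis=1)
    ds = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    Ln = ds[:, None] * S * ds[None, :]
    vals, vecs = np.linalg.eigh(Ln)
    Z = vecs[:, -k:]
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    Z = Z / np.maximum(norms, 1e-12)
    groups, aff = _seeded_kmeans(Z, k)
    groups = _ensure_k_nonempty(groups, k, aff)
    return groups


def mcla(ens: PartitionEnsemble, k: int) -> Partition:
    """Meta-clustering consensus: group hyperedges, collapse, assign.

    Hyperedges (member clusters as indicator columns) are grouped into k
    meta-clusters by spectral partitioning of their Jaccard similarity
    graph; each meta-cluster collapses to the average of its indicators and
    every instance joins the meta-cluster of strongest participation (ties
    break to the lowest meta-cluster index).
    """
    H = hyperedge_matrix(ens)
    groups = _group_hyperedges(_jaccard(H), k)
    k_eff = groups.max() + 1
    assoc = np.column_stack(
        [H[:, groups == g].mean(axis=1) for g in range(k_eff)]
    )
    labels = np.argmax(assoc, axis=1)  # argmax ties -> lowest index
    labels = _ensure_k_nonempty(labels, k_eff, assoc)
    return Partition(labels=labels, k=k, method="mcla")


# ---------------------------------------------------------------------------
# HBGF
# ---------------------------------------------------------------------------


def hbgf(ens: PartitionEnsemble, k: int) -> Partition:
    """Bipartite-graph consensus: spectral partition of the incidence graph.

    Instances and member-clusters are the two vertex sets; an edge links an
    instance to every cluster containing it.  The graph is partitioned into
    k parts by spectral co-clustering and instance labels are read off.
    """
    ens.require_consensus_ready()
    H = hyperedge_matrix(ens)
    labels, aff = _bipartite_spectral(H, k)
    labels = _ensure_k_nonempty(labels, k, aff)
    return Partition(labels=_compact_labels(labels), k=k, method="hbgf")


# ---------------------------------------------------------------------------
# HGPA (approximate)
# ---------------------------------------------------------------------------


def _refine_min_cut(
    labels: np.ndarray, H: np.ndarray, k: int, min_size: int, max_passes: int = 10
) -> np.ndarray:
    """Greedy single-instance moves that reduce the hyperedge cut.

    Moves are accepted only if the donor part keeps >= min_size members
    (the balance constraint); passes repeat until no move improves.
    """
    labels = labels.copy()
    n = labels.shape[0]
    for _ in range(max_passes):
        improved = False
        counts = np.bincount(labels, minlength=k)
        base_cut = hyperedge_cut(labels, H)
        for i in range(n):
            src = labels[i]
            if counts[src] <= min_size:
                continue
            best_c, best_cut = src, base_cut
            for c in range(k):
                if c == src:
                    continue
                labels[i] = c
                cut = hyperedge_cut(labels, H)
                if cut < best_cut:
                    best_c, best_cut = c, cut
            labels[i] = best_c
            if best_c != src:
                counts[src] -= 1
                counts[best_c] += 1
                base_cut = best_cut
                improved = True
        if not improved:
            break
    return labels


def hgpa(ens: PartitionEnsemble, k: int) -> Partition:
    """Approximate hypergraph min-cut consensus ("hgpa-approx").

    Seeks the k-way partition breaking the fewest hyperedges subject to a
    size-balance floor.  Candidate starts (star-expansion spectral embedding
    and the CSPA solution) are refined by balance-constrained local moves;
    the candidate with the smallest hyperedge cut wins.  Exactly k non-empty
    parts are guaranteed.
    """
    ens.require_consensus_ready()
    H = hyperedge_matrix(ens)
    n = H.shape[0]
    min_size = max(1, n // (2 * k))
    # star expansion: down-weight large hyperedges so no cluster dominates
    Hw = H / np.maximum(H.sum(axis=0, keepdims=True), 1.0)
    labels, aff = _bipartite_spectral(Hw, k)
    labels = _ensure_k_nonempty(labels, k, aff)

    candidates = [labels]
    cspa_labels = cspa(ens, k).labels
    if np.bincount(cspa_labels, minlength=k).min() >= min_size:
        candidates.append(cspa_labels)

    best, best_cut = None, np.inf
    for cand in candidates:
        refined = _refine_min_cut(cand, H, k, min_size)
        cut = hyperedge_cut(refined, H)
        if cut < best_cut:
            best, best_cut = refined, cut
    best = _ensure_k_nonempty(best, k, np.zeros((n, k)))
    return Partition(labels=_compact_labels(best), k=k, method="hgpa-approx")


# ---------------------------------------------------------------------------
# ANMI
# ---------------------------------------------------------------------------


def nmi(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized mutual information, 2 I(X;Y) / (H(X) + H(Y)), natural logs.

    Computed from the contingency table of the two labelings; if either side
    has zero entropy (a single cluster) the value is defined as 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("label vectors differ in length")
    n = a.shape[0]
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1.0)
    pxy = table / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    if hx <= 0 or hy <= 0:
        return 0.0
    nz = pxy > 0
    mi = np.sum(pxy[nz] * (np.log(pxy[nz]) - np.log(np.outer(px, py)[nz])))
    return float(2.0 * mi / (hx + hy))


def anmi(candidate: Partition, ens: PartitionEnsemble) -> float:
    """Mean NMI between a candidate consensus and every ensemble member."""
    return float(np.mean([nmi(candidate.labels, p.labels) for p in ens.partitions]))


SOLVERS = {"cspa": cspa, "mcla": mcla, "hbgf": hbgf, "hgpa": hgpa}

__all__ = [
    "ConsensusMatrix", "connectivity", "average_consensus",
    "partition_distance", "hyperedge_matrix", "hyperedge_cut",
    "cspa", "mcla", "hbgf", "hgpa", "nmi", "anmi", "SOLVERS",
]
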