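"""Symmetric-NMF consensus solver and the exhaustive combination search.

The consensus matrix CM~ is factorized as CM~ ~= N L N^T with N (n x k) and
L (k x k) elementwise nonnegative, by alternating multiplicative updates:

    N <- N * (CM N (L + L^T)) / (N L N^T N L^T + N L^T N^T N L)
    L <- L * (N^T CM N) / (N^T N L N^T N)

The L rule is the standard multiplicative step for the quadratic subproblem.
The N rule is the gradient-consistent form of the tri-factorization step:
its numerator/denominator split follows the sign split of the exact gradient
of ||CM - N L N^T||^2, so its fixed points are the KKT points.  Under the
derivation's own working assumptions (CM = N L N^T at the optimum and
near-orthogonal N) the denominator coincides with the looser surrogate
N N^T CM N L sometimes quoted for this scheme; unlike that surrogate, the
gradient-consistent form is observed to be strictly non-increasing (checked
to 1e-9 per step in the tests).  L is not restricted to being diagonal.

For a hard cluster-indicator N with L = N^T N, the column-normalized
N~ = N (N^T N)^{-1/2} satisfies N~ L N~^T = N N^T, so minimizing the relaxed
residual approximates the best hard consensus partition.  Hardening takes
the row-wise argmax; the solver path additionally polishes candidates by
consensus reassignment (coordinate descent on the hard-partition residual)
and keeps the best of several differently-initialized restarts.

The exhaustive search scores every baseline-method subset (size >= 2)
through the full consensus + severity-labeling path over repeated
re-randomized runs, keeps the top-m subsets per run by F-score, and selects
the subset appearing most often across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .baseline_ensemble import Partition, PartitionEnsemble, build_ensemble, child_seed
from .consensus_solvers import ConsensusMatrix, average_consensus
from .motion_io import ValidationError

_EPS = 1e-12  # multiplicative-update denominator floor


@dataclass
class FactorPair:
    """Solved nonnegative factors of CM~ ~= N L N^T with convergence trace."""

    N: np.ndarray
    L: np.ndarray
    trace: list[float]
    n_iter: int
    converged: bool

    @property
    def objective(self) -> float:
        return self.trace[-1]

    def orthogonality_gap(self) -> float:
        """|| N~^T N~ - I ||_F for column-normalized N — soft-orthogonality
        diagnostic (the updates do not renormalize N between iterations)."""
        norms = np.linalg.norm(self.N, axis=0)
        Nn = self.N / np.maximum(norms, _EPS)
        k = self.N.shape[1]
        return float(np.linalg.norm(Nn.T @ Nn - np.eye(k)))


def _objective(cm: np.ndarray, N: np.ndarray, L: np.ndarray) -> float:
    return float(np.linalg.norm(cm - N @ L @ N.T) ** 2)


def _as_cm_array(cm) -> np.ndarray:
    CM = cm.cm if isinstance(cm, ConsensusMatrix) else np.asarray(cm, dtype=float)
    n = CM.shape[0]
    if CM.ndim != 2 or CM.shape != (n, n) or not np.allclose(CM, CM.T, atol=1e-10):
        raise ValidationError("consensus matrix must be square and symmetric")
    return CM


def _cm_scale(CM: np.ndarray) -> float:
    """Scale normalizer: mean diagonal (1 for co-association matrices)."""
    s = float(np.mean(np.diag(CM)))
    if s <= 0:
        s = float(np.mean(np.abs(CM)))
    return s if s > 0 else 1.0


def _init_factors(
    CM: np.ndarray, k: int, rng: np.random.Generator, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Initial (N, L) for one restart.

    ``uniform``: N ~ Uniform(0.1, 1.1); ``spectral``: absolute leading
    eigenvectors of CM (an NNDSVD-style seed); ``indicator``: a random hard
    assignment plus a small positive offset.  L always starts near the
    identity.
    """
    n = CM.shape[0]
    if mode == "uniform":
        N = rng.uniform(0.1, 1.1, size=(n, k))
    elif mode == "spectral":
        _, vecs = np.linalg.eigh(CM)
        N = np.abs(vecs[:, -k:]) + 0.01 * rng.uniform(0.0, 1.0, size=(n, k))
    elif mode == "indicator":
        labels = rng.integers(0, k, size=n)
        N = np.zeros((n, k))
        N[np.arange(n), labels] = 1.0
        N += 0.1 * rng.uniform(0.0, 1.0, size=(n, k))
    else:
        raise ValidationError(f"unknown init mode {mode!r}")
    L = np.eye(k) + 0.01 * rng.uniform(0.0, 1.0, size=(k, k))
    return N, L


def mnmf_solve(
    cm: ConsensusMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
    init: str = "uniform",
) -> FactorPair:
    """Factorize a consensus matrix by the alternating multiplicative rules.

    Iteration stops when the relative objective change drops below ``tol``
    or after ``max_iter`` steps.  The matrix is internally normalized by its
    mean diagonal (a no-op for co-association matrices), which makes the
    trajectory — and hence the hardened partition — exactly invariant to
    positive rescaling of the input; the returned L and objective trace are
    on the original scale.
    """
    CM = _as_cm_array(cm)
    n = CM.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    if max_iter < 1 or tol <= 0:
        raise ValidationError("max_iter >= 1 and tol > 0 required")

    s = _cm_scale(CM)
    CMn = CM / s
    rng = np.random.default_rng(seed)
    N, L = _init_factors(CMn, k, rng, init)

    trace = [_objective(CMn, N, L)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        num = CMn @ N @ (L + L.T)
        den = N @ L @ (N.T @ N) @ L.T + N @ L.T @ (N.T @ N) @ L
        N = N * num / np.maximum(den, _EPS)
        NtN = N.T @ N
        L = L * (N.T @ CMn @ N) / np.maximum(NtN @ L @ NtN, _EPS)
        obj = _objective(CMn, N, L)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break
    # undo the scale normalization: obj(CM, N, s L) = s^2 obj(CM/s, N, L)
    return FactorPair(
        N=N, L=s * L, trace=[s**2 * v for v in trace], n_iter=it, converged=converged
    )


def harden(factors: FactorPair) -> Partition:
    """Hard consensus partition: label(i) = argmax_j N_ij, ties to lowest j.

    Clusters left empty by the argmax are repaired by moving in the instance
    whose margin over the empty cluster's score is weakest.
    """
    N = factors.N
    n, k = N.shape
    labels = np.argmax(N, axis=1)
    for c in range(k):
        if np.any(labels == c):
            continue
        counts = np.bincount(labels, minlength=k)
        movable = counts[labels] > 1
        if not movable.any():
            continue
        cand = np.where(movable)[0]
        margins = N[cand, labels[cand]] - N[cand, c]
        labels[cand[np.argmin(margins)]] = c
    return Partition(labels=labels, k=k, method="psa_mnmf")


def hard_partition_objective(cm: np.ndarray, labels: np.ndarray) -> float:
    """|| CM~ - N N^T ||^2 for the hard indicator N of a labeling.

    For hard indicators N~ L N~^T = N N^T, so this is the objective value
    the relaxed factorization approximates at its hardened solution.
    """
    labels = np.asarray(labels)
    M = (labels[:, None] == labels[None, :]).astype(float)
    return float(np.linalg.norm(np.asarray(cm, dtype=float) - M) ** 2)


def consensus_reassign(
    cm: np.ndarray, labels: np.ndarray, k: int, max_sweeps: int = 100
) -> np.ndarray:
    """Assign each instance to its best consensus cluster until stable.

    Coordinate descent on the hard-partition residual ||CM~ - M||^2: moving
    instance i to cluster c changes the residual by a term proportional to
    n_c - 2 sum_{j in c, j != i} CM~_ij, so each sweep reassigns every
    instance to the cluster maximizing its summed co-association (penalized
    by cluster size).  Moves that would empty a cluster are skipped.
    """
    cm = np.asarray(cm, dtype=float)
    labels = np.asarray(labels, dtype=int).copy()
    n = labels.shape[0]
    for _ in range(max_sweeps):
        moved = False
        for i in range(n):
            counts = np.bincount(labels, minlength=k)
            if counts[labels[i]] <= 1:
                continue
            ind = np.zeros((n, k))
            ind[np.arange(n), labels] = 1.0
            ind[i, :] = 0.0
            S = cm[i] @ ind  # summed co-association of i with each cluster
            sizes = counts.astype(float)
            sizes[labels[i]] -= 1
            # residual contribution (up to constants): sizes - 2 S
            scores = 2 * S - sizes
            best = int(np.argmax(scores))
            if scores[best] > scores[labels[i]] + 1e-12 and best != labels[i]:
                labels[i] = best
                moved = True
        if not moved:
            break
    return labels


def _harden_candidates(factors: FactorPair, k: int) -> list[np.ndarray]:
    """Candidate hard labelings from one solved factor pair.

    The row-wise argmax of N (L + L^T)/2 plus a k-means clustering of the
    row-normalized factor rows (the factor rows are the consensus centroid
    coordinates of the instances).
    """
    from sklearn.cluster import KMeans

    S = factors.N @ (factors.L + factors.L.T) / 2.0
    cands = [np.argmax(S, axis=1)]
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    rows = S / np.maximum(norms, _EPS)
    cands.append(KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(rows))
    return cands


_RESTART_INITS = ("spectral", "uniform", "indicator", "indicator", "indicator")


def mnmf_consensus_from_ensemble(
    ens: PartitionEnsemble,
    k: int,
    seed: int,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> Partition:
    """MNMF consensus of a prebuilt ensemble, best of ``n_restarts``.

    Restarts cycle through spectral, uniform and random-indicator
    initializations; every restart's harden candidates are polished by
    consensus reassignment and the labeling with the smallest hard-partition
    residual wins.  Deterministic given the ensemble and seed, and invariant
    to positive rescaling of the consensus matrix.
    """
    cm = average_consensus(ens)
    s = _cm_scale(cm.cm)
    cm_n = cm.cm / s
    best_labels, best_obj = None, np.inf
    for r in range(n_restarts):
        factors = mnmf_solve(
            cm_n, k, seed=child_seed(seed, 1000 + r), max_iter=max_iter, tol=tol,
            init=_RESTART_INITS[r % len(_RESTART_INITS)],
        )
        for cand in _harden_candidates(factors, k):
            labels = consensus_reassign(cm_n, cand, k)
            obj = hard_partition_objective(cm_n, labels)
            if obj < best_obj - 1e-12:
                best_labels, best_obj = labels, obj
    return Partition(labels=best_labels, k=k, method="psa_mnmf")


def psa_mnmf_consensus(
    X,
    methods: Sequence[str],
    k: int,
    seed: int,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> Partition:
    """Full consensus path: ensemble -> CM~ -> multi-restart MNMF -> harden."""
    ens = build_ensemble(X, methods, k, seed)
    return mnmf_consensus_from_ensemble(ens, k, seed, n_restarts, max_iter, tol)


# ---------------------------------------------------------------------------
# Exhaustive combination search
# ---------------------------------------------------------------------------


@dataclass
class SearchReport:
    """Outcome of the repeated-run exhaustive subset search."""

    top_per_run: list[list[tuple[tuple[str, ...], float]]]
    frequency: dict[tuple[str, ...], int]
    mean_fscore: dict[tuple[str, ...], float]
    selected: tuple[str, ...]
    n_runs: int
    top_m: int
    master_seed: int

    def to_json_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "n_runs": self.n_runs,
            "top_m": self.top_m,
            "master_seed": self.master_seed,
            "frequency": {"+".join(s): c for s, c in self.frequency.items()},
            "mean_fscore": {"+".join(s): v for s, v in self.mean_fscore.items()},
            "top_per_run": [
                [{"subset": list(s), "fscore": f} for s, f in run]
                for run in self.top_per_run
            ],
        }


def method_subsets(methods: Sequence[str]) -> list[tuple[str, ...]]:
    """All subsets of size >= 2, in deterministic order (247 for 8 methods)."""
    methods = list(methods)
    out: list[tuple[str, ...]] = []
    for r in range(2, len(methods) + 1):
        out.extend(itertools.combinations(methods, r))
    return out


def exhaustive_search(
    X,
    all_methods: Sequence[str],
    k: int,
    evaluator: Callable[[Partition], float],
    n_runs: int = 100,
    top_m: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    ensemble_builder: Callable = build_ensemble,
) -> SearchReport:
    """Score every method subset over repeated runs; select the most frequent.

    Per run both the baseline clusterings and the MNMF initialization are
    re-randomized from a fresh run seed.  ``evaluator`` maps a consensus
    partition to its F-score (severity labeling vs FMA-derived truth).  The
    top-``top_m`` subsets per run (F-score descending, ties to earlier
    subset) are tallied; the subset appearing most often wins, ties broken
    by higher mean F-score across all runs.  ``ensemble_builder`` defaults
    to fitting the named baseline methods on X and exists so callers can
    substitute precomputed or synthetic members.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    subsets = method_subsets(all_methods)
    if not subsets:
        raise ValidationError("need >= 2 methods to search over")

    freq: dict[tuple[str, ...], int] = {s: 0 for s in subsets}
    scores_all: dict[tuple[str, ...], list[float]] = {s: [] for s in subsets}
    top_per_run = []
    for run in range(n_runs):
        run_seed = child_seed(seed, run)
        # fit each method once per run, reuse across subsets sharing members
        ens_full = ensemble_builder(X, list(all_methods), k, run_seed)
        by_method = {p.method: p for p in ens_full.partitions}
        scored = []
        for s in subsets:
            ens = PartitionEnsemble([by_method[m] for m in s])
            part = mnmf_consensus_from_ensemble(
                ens, k, run_seed, n_restarts=n_restarts, max_iter=max_iter
            )
            f = float(evaluator(part))
            scored.append((s, f))
            scores_all[s].append(f)
        scored.sort(key=lambda t: -t[1])  # stable: ties keep subset order
        top = scored[:top_m]
        for s, _ in top:
            freq[s] += 1
        top_per_run.append(top)

    mean_f = {s: float(np.mean(v)) if v else 0.0 for s, v in scores_all.items()}
    selected = max(subsets, key=lambda s: (freq[s], mean_f[s]))
    return SearchReport(
        top_per_run=top_per_run,
        frequency={s: c for s, c in freq.items() if c > 0},
        mean_fscore=mean_f,
        selected=selected,
        n_runs=n_runs,
        top_m=top_m,
        master_seed=seed,
    )


__all__ = [
    "FactorPair", "SearchReport", "mnmf_solve", "harden",
    "hard_partition_objective", "consensus_reassign", "psa_mnmf_consensus",
    "mnmf_consensus_from_ensemble", "method_subsets", "exhaustive_search",
]
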