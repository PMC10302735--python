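import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from psamnmf.baseline_ensemble import Partition, PartitionEnsemble
from psamnmf.consensus_solvers import average_consensus
from psamnmf.motion_io import ValidationError
from psamnmf.psa_mnmf import (
    FactorPair,
    consensus_reassign,
    exhaustive_search,
    hard_partition_objective,
    harden,
    method_subsets,
    mnmf_consensus_from_ensemble,
    mnmf_solve,
)
from psamnmf.synthetic_cohort import generate_toy_ensemble


class TestMnmfSolve:
    def test_block_diagonal_exact_factorization(self):
        cm = np.zeros((5, 5))
        cm[:3, :3] = 1.0
        cm[3:, 3:] = 1.0
        factors = mnmf_solve(cm, 2, seed=0, max_iter=2000, tol=1e-12)
        assert factors.objective < 1e-6
        labels = harden(factors).labels
        assert adjusted_rand_score([0, 0, 0, 1, 1], labels) == 1.0

    def test_k1_single_cluster(self):
        ens, _ = generate_toy_ensemble(8, 2, 0.7, 3, seed=0)
        cm = average_consensus(ens)
        factors = mnmf_solve(cm, 1, seed=0)
        labels = harden(factors).labels
        assert set(labels.tolist()) == {0}
        # the only hard partition with one cluster
        assert (
            hard_partition_objective(cm.cm, labels)
            == hard_partition_objective(cm.cm, np.zeros(8, dtype=int))
        )

    def test_objective_trace_non_increasing(self):
        """The multiplicative updates never increase the residual."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            A = rng.random((12, 12))
            A = (A + A.T) / 2
            factors = mnmf_solve(A, 3, seed=seed, max_iter=300, tol=1e-300)
            trace = np.array(factors.trace)
            assert np.max(trace[1:] - trace[:-1]) <= 1e-9

    def test_scale_invariance_of_hardened_partition(self):
        ens, _ = generate_toy_ensemble(12, 2, 0.6, 4, seed=5)
        cm = average_consensus(ens).cm
        base = harden(mnmf_solve(cm, 2, seed=3)).labels
        for c in (0.25, 7.0, 1234.0):
            scaled = harden(mnmf_solve(c * cm, 2, seed=3)).labels
            np.testing.assert_array_equal(base, scaled)

    def test_nonnegativity_preserved(self):
        ens, _ = generate_toy_ensemble(10, 3, 0.5, 3, seed=1)
        factors = mnmf_solve(average_consensus(ens), 3, seed=1)
        assert np.all(factors.N >= 0) and np.all(factors.L >= 0)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError):
            mnmf_solve(np.arange(9.0).reshape(3, 3), 2)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            mnmf_solve(np.eye(3), 4)


class TestHarden:
    def test_tie_goes_to_lowest_column(self):
        N = np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 1.0]])
        factors = FactorPair(N=N, L=np.eye(2), trace=[0.0], n_iter=1, converged=True)
        assert harden(factors).labels.tolist() == [0, 0, 1]

    def test_column_permutation_permutes_labels(self):
        rng = np.random.default_rng(0)
        N = rng.random((8, 3)) + 0.1
        f1 = FactorPair(N=N, L=np.eye(3), trace=[0.0], n_iter=1, converged=True)
        f2 = FactorPair(N=N[:, [2, 0, 1]], L=np.eye(3), trace=[0.0], n_iter=1, converged=True)
        l1, l2 = harden(f1).labels, harden(f2).labels
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_empty_cluster_repaired(self):
        N = np.column_stack([np.ones(5), np.zeros(5)])
        factors = FactorPair(N=N, L=np.eye(2), trace=[0.0], n_iter=1, converged=True)
        labels = harden(factors).labels
        assert set(labels.tolist()) == {0, 1}


class TestConsensusReassign:
    def test_never_increases_objective(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            ens, _ = generate_toy_ensemble(15, 2, 0.5, 3, seed=seed)
            cm = average_consensus(ens).cm
            start = rng.integers(0, 2, 15)
            out = consensus_reassign(cm, start, 2)
            assert hard_partition_objective(cm, out) <= hard_partition_objective(
                cm, start
            ) + 1e-12


class TestConsensusPath:
    def test_small_oracle_equivalence(self):
        """On a 6-point mixed ensemble, restarted solves reach the enumerated
        bipartition optimum of ||CM~ - N N^T||^2 in >= 95 of 100 restarts."""
        ens, _ = generate_toy_ensemble(6, 2, 0.6, 3, seed=0)
        cm = average_consensus(ens).cm
        best = min(
            hard_partition_objective(cm, np.array(p))
            for p in itertools.product([0, 1], repeat=6)
        )
        hits = 0
        for restart in range(100):
            labels = consensus_reassign(
                cm, harden(mnmf_solve(cm, 2, seed=restart)).labels, 2
            )
            hits += hard_partition_objective(cm, labels) <= best + 1e-9
        assert hits >= 95

    def test_deterministic_under_seed(self):
        ens, _ = generate_toy_ensemble(15, 2, 0.6, 4, seed=2)
        a = mnmf_consensus_from_ensemble(ens, 2, seed=7).labels
        b = mnmf_consensus_from_ensemble(ens, 2, seed=7).labels
        np.testing.assert_array_equal(a, b)

    def test_consensus_tracks_majority_not_corrupted_member(self):
        rng = np.random.default_rng(0)
        truth = np.repeat([0, 1], 15)
        aris = []
        for trial in range(10):
            members = [
                Partition(labels=truth.copy(), k=2, method=f"g{i}") for i in range(3)
            ]
            members.append(
                Partition(labels=rng.integers(0, 2, 30), k=2, method="noise")
            )
            ens = PartitionEnsemble(members)
            part = mnmf_consensus_from_ensemble(ens, 2, seed=trial)
            aris.append(adjusted_rand_score(truth, part.labels))
        assert np.mean(aris) >= 0.95


class TestExhaustiveSearch:
    def test_subset_enumeration(self):
        assert len(method_subsets(["a", "b", "c"])) == 4
        assert len(method_subsets(list("abcdefgh"))) == 247

    @staticmethod
    def _planted_builder(truth, rng_factory):
        def build(X, methods, k, seed):
            rng = np.random.default_rng(seed)
            members = []
            for m in methods:
                if m == "random":
                    labels = rng.integers(0, k, truth.shape[0])
                else:
                    labels = truth.copy()
                members.append(Partition(labels=labels, k=k, method=m))
            return PartitionEnsemble(members)

        return build

    def test_random_member_excluded(self):
        """Planted-truth members dominate the top lists; the selected subset
        drops the random member."""
        truth = np.repeat([0, 1], 12)

        def evaluator(part):
            return adjusted_rand_score(truth, part.labels)

        report = exhaustive_search(
            X=None,
            all_methods=["A", "B", "random"],
            k=2,
            evaluator=evaluator,
            n_runs=5,
            top_m=1,
            seed=0,
            ensemble_builder=self._planted_builder(truth, None),
        )
        assert "random" not in report.selected

    def test_report_reproducible(self):
        truth = np.repeat([0, 1], 8)

        def evaluator(part):
            return adjusted_rand_score(truth, part.labels)

        kwargs = dict(
            X=None,
            all_methods=["A", "B", "random"],
            k=2,
            evaluator=evaluator,
            n_runs=3,
            top_m=2,
            seed=5,
            ensemble_builder=self._planted_builder(truth, None),
        )
        r1 = exhaustive_search(**kwargs)
        r2 = exhaustive_search(**kwargs)
        assert r1.to_json_dict() == r2.to_json_dict()
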