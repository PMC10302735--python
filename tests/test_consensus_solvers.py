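import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from psamnmf.baseline_ensemble import Partition, PartitionEnsemble
from psamnmf.consensus_solvers import (
    SOLVERS,
    anmi,
    average_consensus,
    connectivity,
    cspa,
    hbgf,
    hgpa,
    hyperedge_cut,
    hyperedge_matrix,
    mcla,
    nmi,
    partition_distance,
)
from psamnmf.psa_mnmf import hard_partition_objective, mnmf_consensus_from_ensemble
from psamnmf.synthetic_cohort import generate_toy_ensemble


def _p(labels, k=None, method="m"):
    labels = np.asarray(labels)
    return Partition(labels=labels, k=k or labels.max() + 1, method=method)


class TestConnectivity:
    def test_two_blocks(self):
        M = connectivity(_p([0, 0, 1, 1]))
        expected = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        np.testing.assert_array_equal(M, expected)

    def test_single_cluster_all_ones(self):
        np.testing.assert_array_equal(connectivity(_p([0, 0, 0], k=1)), 1.0)

    def test_singletons_identity(self):
        np.testing.assert_array_equal(connectivity(_p([0, 1, 2])), np.eye(3))


class TestAverageConsensus:
    def test_identical_members(self):
        ens = PartitionEnsemble([_p([0, 1, 0, 1]), _p([0, 1, 0, 1])])
        cm = average_consensus(ens)
        np.testing.assert_array_equal(cm.cm, connectivity(ens.partitions[0]))
        assert cm.dispersion == 0.0

    def test_mixed_pair(self):
        ens = PartitionEnsemble([_p([0, 0, 1]), _p([0, 1, 1])])
        cm = average_consensus(ens)
        np.testing.assert_allclose(
            cm.cm, [[1, 0.5, 0], [0.5, 1, 0.5], [0, 0.5, 1]]
        )

    def test_dispersion_matches_brute_force(self):
        rng = np.random.default_rng(0)
        members = [_p(rng.integers(0, 3, 12), k=3) for _ in range(4)]
        ens = PartitionEnsemble(members)
        cm = average_consensus(ens)
        brute = np.mean(
            [
                sum(
                    (connectivity(p)[i, j] - cm.cm[i, j]) ** 2
                    for i in range(12)
                    for j in range(12)
                )
                for p in members
            ]
        )
        assert abs(cm.dispersion - brute) < 1e-9

    def test_entries_on_grid(self):
        rng = np.random.default_rng(1)
        ens = PartitionEnsemble([_p(rng.integers(0, 2, 10), k=2) for _ in range(5)])
        cm = average_consensus(ens)
        np.testing.assert_allclose(np.round(cm.cm * 5), cm.cm * 5, atol=1e-12)


class TestPartitionDistance:
    def test_self_distance_zero(self):
        p = _p([0, 1, 0, 2])
        assert partition_distance(p, p) == 0

    def test_hand_example(self):
        # pairs (1,2) and (2,3) disagree, counted in both orders
        assert partition_distance(_p([0, 0, 1]), _p([0, 1, 1])) == 4

    def test_relabel_invariance(self):
        p1, p2 = _p([0, 0, 1]), _p([0, 1, 1])
        assert partition_distance(p1, p2) == partition_distance(p1, _p([1, 0, 0]))

    def test_pseudometric_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a, b, c = (_p(rng.integers(0, 3, 10), k=3) for _ in range(3))
            dab = partition_distance(a, b)
            assert dab == partition_distance(b, a)
            assert dab <= partition_distance(a, c) + partition_distance(c, b)


def _unanimous(n, k, T, seed):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
    rng.shuffle(labels)
    return (
        PartitionEnsemble([_p(labels.copy(), k=k, method=f"m{t}") for t in range(T)]),
        labels,
    )


ALL_SOLVERS = dict(SOLVERS)
ALL_SOLVERS["psa_mnmf"] = lambda ens, k: mnmf_consensus_from_ensemble(ens, k, seed=0)


@pytest.mark.parametrize("name", sorted(ALL_SOLVERS))
def test_unanimity_recovery(name):
    """Zero-dispersion ensembles are recovered exactly by every solver."""
    for seed in range(5):
        ens, truth = _unanimous(30, 2 + seed % 2, 4, seed)
        assert average_consensus(ens).dispersion == 0.0
        out = ALL_SOLVERS[name](ens, 2 + seed % 2)
        assert adjusted_rand_score(truth, out.labels) == 1.0


@pytest.mark.parametrize("name", sorted(ALL_SOLVERS))
def test_member_label_permutation_invariance(name):
    ens, _ = generate_toy_ensemble(20, 2, 0.7, 4, seed=3)
    base = ALL_SOLVERS[name](ens, 2).labels
    permuted = [p for p in ens.partitions]
    permuted[1] = _p(1 - permuted[1].labels, k=2, method=permuted[1].method)
    out = ALL_SOLVERS[name](PartitionEnsemble(permuted), 2).labels
    assert adjusted_rand_score(base, out) == 1.0


@pytest.mark.parametrize("name", sorted(ALL_SOLVERS))
def test_member_order_invariance(name):
    ens, _ = generate_toy_ensemble(20, 2, 0.7, 4, seed=8)
    base = ALL_SOLVERS[name](ens, 2).labels
    out = ALL_SOLVERS[name](PartitionEnsemble(ens.partitions[::-1]), 2).labels
    assert adjusted_rand_score(base, out) == 1.0


class TestCSPA:
    def test_three_point_tie(self):
        ens = PartitionEnsemble([_p([0, 0, 1]), _p([0, 1, 1])])
        labels = cspa(ens, 2).labels
        assert tuple(labels) in {(0, 0, 1), (0, 1, 1)}


class TestMCLA:
    def test_single_member_identity(self):
        member = _p([0, 1, 0, 2, 1], k=3)
        out = mcla(PartitionEnsemble([member]), 3)
        assert adjusted_rand_score(member.labels, out.labels) == 1.0

    def test_majority_structure_with_corrupted_member(self):
        truth = np.array([0, 0, 0, 1, 1, 1])
        good = [_p(truth.copy(), k=2, method=f"g{i}") for i in range(2)]
        bad = _p(np.array([0, 1, 0, 1, 0, 1]), k=2, method="bad")
        ens = PartitionEnsemble(good + [bad])
        cm = average_consensus(ens).cm
        # brute-force best hard bipartition of the consensus matrix
        best = min(
            (np.array(p) for p in itertools.product([0, 1], repeat=6)),
            key=lambda lab: hard_partition_objective(cm, lab),
        )
        out = mcla(ens, 2)
        assert adjusted_rand_score(best, out.labels) == 1.0


class TestHBGF:
    def test_incidence_shape(self):
        ens, _ = generate_toy_ensemble(15, 3, 1.0, 4, seed=0)
        H = hyperedge_matrix(ens)
        assert H.shape == (15, sum(p.k for p in ens.partitions))

    def test_agrees_with_cspa_when_dispersion_zero(self):
        ens, _ = _unanimous(40, 3, 5, seed=2)
        a = hbgf(ens, 3).labels
        b = cspa(ens, 3).labels
        assert adjusted_rand_score(a, b) == 1.0


class TestHGPA:
    def test_exactly_k_nonempty_parts(self):
        for seed in range(4):
            ens, _ = generate_toy_ensemble(24, 2, 0.6, 4, seed=seed)
            out = hgpa(ens, 2)
            assert len(set(out.labels.tolist())) == 2

    def test_cut_not_worse_than_cspa(self):
        """When the CSPA solution meets the balance floor, the min-cut
        refinement can only match or beat its hyperedge cut."""
        checked = 0
        for seed in range(6):
            ens, _ = generate_toy_ensemble(24, 2, 0.65, 4, seed=seed)
            H = hyperedge_matrix(ens)
            cut_cspa = hyperedge_cut(cspa(ens, 2).labels, H)
            counts = np.bincount(cspa(ens, 2).labels, minlength=2)
            if counts.min() >= 24 // 4:
                cut_h = hyperedge_cut(hgpa(ens, 2).labels, H)
                assert cut_h <= cut_cspa
                checked += 1
        assert checked >= 3


class TestANMI:
    def test_identical_is_one(self):
        ens, truth = _unanimous(20, 2, 3, seed=0)
        assert anmi(_p(truth, k=2), ens) == pytest.approx(1.0)

    def test_independent_four_points_is_zero(self):
        ens = PartitionEnsemble([_p([0, 1, 0, 1])])
        assert anmi(_p([0, 0, 1, 1]), ens) == 0.0

    def test_mean_of_pairwise_nmi(self):
        rng = np.random.default_rng(4)
        cand = _p(rng.integers(0, 2, 30), k=2)
        members = [_p(rng.integers(0, 3, 30), k=3) for _ in range(2)]
        ens = PartitionEnsemble(members)
        expect = np.mean([nmi(cand.labels, m.labels) for m in members])
        assert anmi(cand, ens) == pytest.approx(expect, abs=1e-15)

    def test_matches_sklearn_contingency_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.integers(0, 3, 40)
            b = rng.integers(0, 4, 40)
            ours = nmi(a, b)
            ref = normalized_mutual_info_score(a, b, average_method="arithmetic")
            assert abs(ours - ref) < 1e-12

    def test_zero_entropy_side(self):
        assert nmi(np.zeros(10, dtype=int), np.arange(10) % 2) == 0.0
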