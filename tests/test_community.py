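"""Modularity, its optimization, partition matching and distances."""

import numpy as np
import pytest

from spnnet import (
    ConnectivityMatrix,
    Partition,
    build_connectivity_matrix,
    match_partitions,
    newman_modularity,
    optimize_modularity,
    partition_distance,
    partition_distance_test,
)
from conftest import make_graph
from oracles import (
    modularity_double_loop,
    random_weighted_graph,
    set_partitions,
    vi_from_contingency,
)


def two_cliques(k=4, weight=1.0):
    n = 2 * k
    w = np.zeros((n, n))
    for block in (range(k), range(k, n)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = weight
    return make_graph(w)


def part(labels, ids=None):
    labels = np.asarray(labels)
    ids = ids or [f"n{i}" for i in range(len(labels))]
    return Partition(node_ids=ids, labels=labels)


class TestNewmanModularity:
    def test_single_module_is_zero(self, rng):
        w = random_weighted_graph(rng, 8)
        assert newman_modularity(make_graph(w), np.zeros(8, int)) == pytest.approx(0.0)

    def test_two_disconnected_cliques_split_gives_half(self):
        g = two_cliques()
        labels = np.array([0] * 4 + [1] * 4)
        assert newman_modularity(g, labels) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        w = random_weighted_graph(rng, 11)
        labels = rng.integers(0, 4, size=11)
        g = make_graph(w)
        assert newman_modularity(g, labels) == pytest.approx(
            modularity_double_loop(w, labels), abs=1e-12
        )

    def test_unlabeled_node_rejected(self, rng):
        g = make_graph(random_weighted_graph(rng, 5))
        with pytest.raises(ValueError):
            newman_modularity(g, np.zeros(4, int))


class TestOptimizeModularity:
    def test_recovers_disconnected_cliques(self):
        g = two_cliques()
        p = optimize_modularity(g, n_runs=10, seed=0)
        assert p.q == pytest.approx(0.5)
        assert np.array_equal(p.labels, [0] * 4 + [1] * 4)

    def test_complete_graph_single_module(self):
        w = np.ones((6, 6)) - np.eye(6)
        p = optimize_modularity(make_graph(w), n_runs=5, seed=1)
        assert p.n_modules == 1
        assert p.q == pytest.approx(0.0)

    def test_stored_q_recomputable(self, rng):
        g = make_graph(random_weighted_graph(rng, 12))
        p = optimize_modularity(g, n_runs=10, seed=3)
        assert newman_modularity(g, p.labels) == pytest.approx(p.q, abs=1e-12)

    def test_beats_trivial_partitions(self, rng):
        for _ in range(5):
            n = int(rng.integers(6, 14))
            g = make_graph(random_weighted_graph(rng, n))
            p = optimize_modularity(g, n_runs=10, seed=7)
            assert p.q >= newman_modularity(g, np.zeros(n, int)) - 1e-12
            assert p.q >= newman_modularity(g, np.arange(n)) - 1e-12

    def test_deterministic_under_fixed_seed(self, rng):
        g = make_graph(random_weighted_graph(rng, 10))
        p1 = optimize_modularity(g, n_runs=8, seed=42)
        p2 = optimize_modularity(g, n_runs=8, seed=42)
        assert np.array_equal(p1.labels, p2.labels) and p1.q == p2.q

    def test_attains_exhaustive_optimum_on_small_graphs(self):
        """Best-of-100 matches the Bell-number enumeration optimum on
        >= 95 of 100 seeded 7-node graphs."""
        rng = np.random.default_rng(42)
        wins, total = 0, 0
        for trial in range(100):
            w = random_weighted_graph(rng, 7, p_edge=0.5)
            g = make_graph(w)
            best = max(
                newman_modularity(g, np.array(p)) for p in set_partitions(7)
            )
            found = optimize_modularity(g, n_runs=100, seed=trial).q
            total += 1
            if abs(found - best) < 1e-10:
                wins += 1
        assert wins >= 95, f"optimal in only {wins}/{total} graphs"


class TestMatchPartitions:
    def test_label_shuffle_is_inverted(self, rng):
        labels = rng.integers(0, 4, size=12)
        ref = part(labels)
        shuffled = part((labels + 2) % 4)
        matched = match_partitions(ref, shuffled)
        assert np.array_equal(matched.labels, ref.canonicalize().labels)

    def test_overlap_equals_bruteforce_permutation_optimum(self):
        from oracles import best_label_permutation_overlap

        rng = np.random.default_rng(13)
        for _ in range(10):
            l1 = rng.integers(0, 3, size=10)
            l2 = rng.integers(0, 4, size=10)
            ref, other = part(l1), part(l2)
            matched = match_partitions(ref, other)
            overlap = int(np.sum(ref.canonicalize().labels == matched.labels))
            assert overlap == best_label_permutation_overlap(
                ref.canonicalize().labels, other.canonicalize().labels
            )

    def test_idempotent(self, rng):
        ref = part(rng.integers(0, 3, size=9))
        other = part(rng.integers(0, 3, size=9))
        once = match_partitions(ref, other)
        twice = match_partitions(ref, once)
        assert np.array_equal(once.labels, twice.labels)

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_partitions(part([0, 1], ids=["a", "b"]), part([0, 1], ids=["a", "c"]))


class TestPartitionDistance:
    def test_identical_partitions(self, rng):
        p = part(rng.integers(0, 3, size=10))
        assert partition_distance(p, p) == 0.0

    def test_extreme_case_is_one(self):
        n = 6
        assert partition_distance(
            part(np.zeros(n, int)), part(np.arange(n))
        ) == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # {AB|CD} vs {AC|BD}: VI = 2*log2, normalized by log 4 -> 1.0
        p1 = part([0, 0, 1, 1])
        p2 = part([0, 1, 0, 1])
        vi = vi_from_contingency(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
        assert partition_distance(p1, p2) == pytest.approx(vi / np.log(4), abs=1e-12)
        assert partition_distance(p1, p2) == pytest.approx(1.0)

    def test_metric_properties_on_random_partitions(self, rng):
        """Symmetry, identity of indiscernibles and triangle inequality."""
        for _ in range(30):
            n = int(rng.integers(4, 12))
            a = part(rng.integers(0, 3, size=n))
            b = part(rng.integers(0, 3, size=n), ids=a.node_ids)
            c = part(rng.integers(0, 3, size=n), ids=a.node_ids)
            dab = partition_distance(a, b)
            assert dab == pytest.approx(partition_distance(b, a), abs=1e-12)
            if np.array_equal(a.canonicalize().labels, b.canonicalize().labels):
                assert dab == pytest.approx(0.0, abs=1e-12)
            assert dab <= partition_distance(a, c) + partition_distance(c, b) + 1e-12


def _random_cm(rng, n, label):
    w = np.triu(rng.random((n, n)), 1)
    return ConnectivityMatrix(weights=w + w.T, label=label)


def _modular_cm(rng, n, labels, hi=0.8, lo=0.1, label="s"):
    """Subject matrix with planted block structure plus light noise."""
    same = labels[:, None] == labels[None, :]
    base = np.where(same, hi, lo) + rng.normal(0, 0.02, size=(n, n))
    w = np.triu(np.clip(base, 0, 1), 1)
    return ConnectivityMatrix(weights=w + w.T, label=label)


class TestPartitionDistanceTest:
    def test_identical_groups_give_p_one(self, rng):
        mats = [_random_cm(rng, 8, f"s{i}") for i in range(4)]
        d, p = partition_distance_test(mats, list(mats), n_perm=9, n_runs=4, seed=0)
        assert d == pytest.approx(0.0)
        assert p == 1.0

    def test_planted_structural_difference_detected(self):
        """A two-module majority group against a smaller three-module
        group (unbalanced sizes, like a patient-control design): the
        observed distance is large and the permutation p small, since
        label exchanges rarely concentrate enough minority subjects on
        one side to reproduce the structural split."""
        rng = np.random.default_rng(21)
        n = 18
        la = np.repeat([0, 1], 9)
        lb = np.repeat([0, 1, 2], 6)
        mats_a = [_modular_cm(rng, n, la, hi=0.8, label=f"a{i}") for i in range(18)]
        mats_b = [_modular_cm(rng, n, lb, hi=0.6, label=f"b{i}") for i in range(6)]
        d, p = partition_distance_test(mats_a, mats_b, n_perm=199, n_runs=8, seed=0)
        assert d > 0.2
        assert p <= 0.05

    def test_null_calibration_scaled_down(self):
        """With exchangeable groups the test rejects at roughly the nominal
        rate (wide band, small n_perm, few repetitions)."""
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 25
        for r in range(reps):
            pool = [_random_cm(rng, 7, f"s{i}") for i in range(8)]
            d, p = partition_distance_test(
                pool[:4], pool[4:], n_perm=19, n_runs=3, seed=r
            )
            if p <= 0.05:
                rejections += 1
        assert rejections <= 3  # ~binomial(25, 0.05) upper tail

    def test_invalid_n_perm_rejected(self, rng):
        mats = [_random_cm(rng, 6, f"s{i}") for i in range(4)]
        with pytest.raises(ValueError):
            partition_distance_test(mats[:2], mats[2:], n_perm=0)
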