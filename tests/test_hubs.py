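"""Participation coefficients, the hub taxonomy, and the homogeneity test."""

import numpy as np
import pytest

from spnnet import (
    HubCensus,
    Partition,
    classify_nodes,
    hub_census,
    hub_homogeneity_test,
    participation_coefficient,
)
from spnnet.hubs import CATEGORIES
from conftest import make_graph
from oracles import chi2_loop, participation_loop, random_weighted_graph


def part_for(g, labels):
    return Partition(node_ids=list(g.node_ids), labels=np.asarray(labels))


def census(c=0, p=0, h=0, n=0):
    return HubCensus(counts={"connector_hub": c, "provincial_hub": p,
                             "high_influence": h, "normal": n})


class TestParticipation:
    def test_all_weight_within_own_module_is_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.8
        w[2, 3] = w[3, 2] = 0.5
        g = make_graph(w)
        p = participation_coefficient(g, part_for(g, [0, 0, 1, 1]))
        assert np.all(p == 0)

    def test_equal_split_across_m_modules(self):
        # center node 0 connects with equal weight to one node per module
        m = 4
        w = np.zeros((m + 1, m + 1))
        w[0, 1:] = w[1:, 0] = 0.3
        g = make_graph(w)
        labels = [0] + list(range(1, m + 1))
        p = participation_coefficient(g, part_for(g, labels))
        assert p[0] == pytest.approx(1 - 1 / m)

    def test_matches_per_module_loop_oracle(self):
        rng = np.random.default_rng(12)
        w = random_weighted_graph(rng, 11)
        labels = rng.integers(0, 3, size=11)
        g = make_graph(w)
        assert np.allclose(
            participation_coefficient(g, part_for(g, labels)),
            participation_loop(w, labels),
            atol=1e-12,
        )

    def test_bounded_by_module_count(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 14))
            w = random_weighted_graph(rng, n)
            m = int(rng.integers(1, 5))
            labels = rng.integers(0, m, size=n)
            g = make_graph(w)
            p = participation_coefficient(g, part_for(g, labels))
            m_eff = len(np.unique(labels))
            assert np.all(p >= 0) and np.all(p <= 1 - 1 / m_eff + 1e-12)

    def test_isolated_node_gets_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        g = make_graph(w)
        p = participation_coefficient(g, part_for(g, [0, 1, 1]))
        assert p[2] == 0.0


class TestClassifyNodes:
    def star(self, n=10):
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        return make_graph(w)

    def test_star_center_is_provincial_hub(self):
        """Degree 9 vs mean 1.8 (SD ~2.53) makes the center a hub; with a
        single module every P is 0, so it stays provincial."""
        g = self.star()
        profs = classify_nodes(g, part_for(g, np.zeros(10, int)))
        assert profs[0].category == "provincial_hub"
        assert profs[0].pillar  # 9/10 >= 1.8/10 + 1.5*sd as well
        assert all(p.category != "connector_hub" for p in profs)

    def test_regular_ring_has_no_hubs_or_high_influence(self):
        n = 8
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 0.5
        g = make_graph(w)
        profs = classify_nodes(g, part_for(g, np.zeros(n, int)))
        assert {p.category for p in profs} == {"normal"}

    def test_pillars_are_always_hubs(self):
        rng = np.random.default_rng(0)
        for seed in range(200):
            w = random_weighted_graph(rng, int(rng.integers(5, 15)))
            g = make_graph(w)
            labels = rng.integers(0, 3, size=w.shape[0])
            for p in classify_nodes(g, part_for(g, labels)):
                if p.pillar:
                    assert p.category in ("connector_hub", "provincial_hub")

    def test_categories_exhaustive_and_exclusive(self, rng):
        w = random_weighted_graph(rng, 12)
        g = make_graph(w)
        profs = classify_nodes(g, part_for(g, rng.integers(0, 3, size=12)))
        assert len(profs) == 12
        assert all(p.category in CATEGORIES for p in profs)

    def test_scale_invariance(self, rng):
        w = random_weighted_graph(rng, 10)
        labels = rng.integers(0, 3, size=10)
        g1, g2 = make_graph(w), make_graph(4.2 * w)
        cats1 = [p.category for p in classify_nodes(g1, part_for(g1, labels))]
        cats2 = [p.category for p in classify_nodes(g2, part_for(g2, labels))]
        assert cats1 == cats2

    def test_raising_hub_sd_never_adds_hubs(self, rng):
        w = random_weighted_graph(rng, 15)
        g = make_graph(w)
        labels = rng.integers(0, 3, size=15)

        def hub_count(sd):
            return sum(p.category in ("connector_hub", "provincial_hub")
                       for p in classify_nodes(g, part_for(g, labels), hub_sd=sd))

        counts = [hub_count(sd) for sd in (0.5, 1.0, 1.5, 2.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_degenerate_zero_variance_all_normal(self):
        w = np.ones((4, 4)) - np.eye(4)
        g = make_graph(w)
        profs = classify_nodes(g, part_for(g, np.zeros(4, int)))
        assert {p.category for p in profs} == {"normal"}
        assert not any(p.pillar for p in profs)


class TestCensusAndHomogeneity:
    def test_counts_sum_to_n(self, rng):
        w = random_weighted_graph(rng, 13)
        g = make_graph(w)
        c = hub_census(classify_nodes(g, part_for(g, rng.integers(0, 3, 13))))
        assert c.n_nodes == 13

    def test_star_census(self):
        g = TestClassifyNodes().star()
        c = hub_census(classify_nodes(g, part_for(g, np.zeros(10, int))))
        assert c.counts["connector_hub"] == 0
        assert c.counts["provincial_hub"] == 1

    def test_identical_censuses_give_zero_chi2(self):
        a = census(c=3, p=5, h=10, n=82)
        chi2, df, p = hub_homogeneity_test(a, a)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_printed_patient_condition_contrast(self):
        """45 vs 44 provincial hubs of 212 nodes with no other hub
        categories: chi2 rounds to 0.01 at df = 1."""
        a = census(p=45, n=167)
        b = census(p=44, n=168)
        chi2, df, p = hub_homogeneity_test(a, b)
        assert round(chi2, 2) == 0.01
        assert df == 1
        assert p > 0.9

    def test_matches_expected_count_loop_oracle(self):
        rng = np.random.default_rng(30)
        for _ in range(10):
            va = rng.integers(1, 40, size=4)
            vb = rng.integers(1, 40, size=4)
            n = int(max(va.sum(), vb.sum()))
            a = census(*(va.tolist()[:3] + [n - int(va[:3].sum())]))
            b = census(*(vb.tolist()[:3] + [n - int(vb[:3].sum())]))
            chi2, df, _ = hub_homogeneity_test(a, b)
            table = np.vstack([a.as_vector(), b.as_vector()])
            table = table[:, table.sum(axis=0) > 0]
            assert chi2 == pytest.approx(chi2_loop(table), abs=1e-12)

    def test_single_shared_category_is_degenerate(self):
        with pytest.raises(ValueError):
            hub_homogeneity_test(census(n=10), census(n=10))

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError):
            hub_homogeneity_test(census(n=10), census(n=12))
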