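"""Grading scheme, stratified sampling, neighbour positivity and rank tests."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

import lcqspatial as L
from lcqspatial.synthetic_tissue import LobuleAdjacency


def make_adjacency(edges, lobule_of):
    g = nx.Graph()
    for node, lob in lobule_of.items():
        g.add_node(node, lobule_id=lob)
    g.add_edges_from(edges)
    return LobuleAdjacency(graph=g)


def make_grades(positivity):
    return [
        L.grade_alveolus(10 if pos else 0, 20, alveolus_id=aid)
        for aid, pos in positivity.items()
    ]


class TestGrading:
    @pytest.mark.parametrize(
        "n_pos, n_epi, grade",
        [
            (0, 20, 1),
            (5, 20, 1),   # exactly 25% stays grade 1
            (6, 20, 2),
            (10, 20, 2),  # exactly 50% stays grade 2
            (11, 20, 3),
            (15, 20, 3),  # exactly 75% stays grade 3
            (16, 20, 4),
            (20, 20, 4),
            (1, 3, 2),
        ],
    )
    def test_grade_bands(self, n_pos, n_epi, grade):
        g = L.grade_alveolus(n_pos, n_epi)
        assert g.grade == grade
        assert g.any_positive == (n_pos >= 1)
        assert g.fraction_positive == pytest.approx(n_pos / n_epi)

    def test_zero_epithelial_cells_undefined(self):
        with pytest.raises(L.ComputationError, match="grade undefined"):
            L.grade_alveolus(0, 0)

    @given(n_epi=st.integers(1, 60), data=st.data())
    def test_grade_monotone_in_positive_count(self, n_epi, data):
        k = data.draw(st.integers(0, n_epi - 1))
        g1 = L.grade_alveolus(k, n_epi)
        g2 = L.grade_alveolus(k + 1, n_epi)
        assert g2.grade >= g1.grade
        assert 1 <= g1.grade <= 4


class TestSampling:
    def _grades(self, n_pos, n_neg):
        pos = [L.grade_alveolus(5, 20, alveolus_id=i) for i in range(n_pos)]
        neg = [L.grade_alveolus(0, 20, alveolus_id=1000 + i) for i in range(n_neg)]
        return pos + neg

    def test_stratified_disjoint_and_reproducible(self):
        grades = self._grades(40, 40)
        p1, n1 = L.sample_alveoli(grades, 25, seed=3)
        p2, n2 = L.sample_alveoli(grades, 25, seed=3)
        assert len(p1) == len(n1) == 25
        ids = {g.alveolus_id for g in p1} | {g.alveolus_id for g in n1}
        assert len(ids) == 50
        assert all(g.any_positive for g in p1)
        assert not any(g.any_positive for g in n1)
        assert [g.alveolus_id for g in p1] == [g.alveolus_id for g in p2]
        assert [g.alveolus_id for g in n1] == [g.alveolus_id for g in n2]

    def test_small_stratum_reports_available_count(self):
        grades = self._grades(7, 40)
        with pytest.raises(L.ComputationError, match="only 7"):
            L.sample_alveoli(grades, 25, seed=1)


class TestGradeDistribution:
    def test_direct_counts_and_extremity(self):
        grades = [L.grade_alveolus(k, 20, alveolus_id=k) for k in (0, 8, 12, 20)]
        dist = L.grade_distribution(grades)
        assert dist.counts == (1, 1, 1, 1)
        assert dist.extremity_fraction == 0.5

    def test_all_grade_four(self):
        grades = [L.grade_alveolus(20, 20, alveolus_id=i) for i in range(6)]
        dist = L.grade_distribution(grades)
        assert dist.counts == (0, 0, 0, 6)
        assert dist.extremity_fraction == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(L.ComputationError):
            L.grade_distribution([])

    def test_single_gland_matches_binomial_mixture(self, default_gland):
        """One default gland's histogram vs the exact two-state binomial
        mixture, with lobule-clustered standard errors."""
        cfg, pattern, alveoli, _, _ = default_gland
        dist = L.grade_distribution(L.grade_alveoli(pattern, alveoli))
        edges = [5, 10, 15]

        def bin_probs(p):
            cdf = [binom.cdf(e, 20, p) for e in edges]
            return np.array([cdf[0], cdf[1] - cdf[0], cdf[2] - cdf[1], 1 - cdf[2]])

        bc, bu = bin_probs(cfg.p_cell_high), bin_probs(cfg.p_cell_low)
        f = cfg.commitment_fraction
        q_hi = cfg.within_lobule_commit_prob_high
        q_lo = cfg.within_lobule_commit_prob_low
        pi = (f * q_hi + (1 - f) * q_lo) * bc + (1 - (f * q_hi + (1 - f) * q_lo)) * bu
        n_alv, m = len(alveoli), 10
        mean_l = np.zeros(4)
        var_l = np.zeros(4)
        for state_p, q in ((f, q_hi), (1 - f, q_lo)):
            pis = q * bc + (1 - q) * bu
            mean_l += state_p * m * pis
            var_l += state_p * (m * pis * (1 - pis) + (m * pis) ** 2)
        var_l -= mean_l**2
        sd = np.sqrt((n_alv / m) * var_l)
        observed = np.array(dist.counts)
        assert np.all(np.abs(observed - n_alv * pi) <= 3 * sd + 1e-9)


class TestNeighbourPositivity:
    def test_extremes(self):
        adj = make_adjacency(
            [(1, 2), (1, 3), (1, 4), (1, 5)], {i: 1 for i in range(1, 6)}
        )
        all_neg = make_grades({i: False for i in range(1, 6)})
        st0 = L.neighbour_positivity(1, adj, all_neg)
        assert st0.pct_positive_neighbours == 0.0
        all_pos = make_grades({i: True for i in range(1, 6)})
        st100 = L.neighbour_positivity(1, adj, all_pos)
        assert st100.pct_positive_neighbours == 100.0
        assert st100.n_neighbours == 4

    def test_hand_built_lobule(self):
        """5 alveoli, edges and labels fixed by hand; percentages by hand count."""
        edges = [(1, 2), (1, 3), (2, 3), (3, 4), (4, 5)]
        adj = make_adjacency(edges, {i: 1 for i in range(1, 6)})
        grades = make_grades({1: True, 2: False, 3: True, 4: False, 5: True})
        # neighbours of 3 are {1, 2, 4}: one positive -> 33.33%
        st3 = L.neighbour_positivity(3, adj, grades)
        assert st3.n_neighbours == 3
        assert st3.pct_positive_neighbours == pytest.approx(100.0 / 3.0)
        # neighbours of 4 are {3, 5}: both positive -> 100%
        st4 = L.neighbour_positivity(4, adj, grades)
        assert st4.pct_positive_neighbours == 100.0

    def test_isolated_seed_dropped_not_fatal(self):
        adj = make_adjacency([(1, 2)], {1: 1, 2: 1, 3: 2})
        grades = make_grades({1: True, 2: True, 3: True})
        assert L.neighbour_positivity(3, adj, grades) is None
        stats = L.neighbour_table(grades, adj, grades)
        assert len(stats) == 2

    @given(st.lists(st.booleans(), min_size=1, max_size=12))
    def test_removing_negative_neighbour_never_lowers_pct(self, labels):
        nodes = {0: 1, **{i + 1: 1 for i in range(len(labels))}}
        edges = [(0, i + 1) for i in range(len(labels))]
        adj = make_adjacency(edges, nodes)
        grades = make_grades({0: False, **{i + 1: l for i, l in enumerate(labels)}})
        st_full = L.neighbour_positivity(0, adj, grades)
        if False in labels and len(labels) > 1:
            drop = labels.index(False) + 1
            adj.graph.remove_node(drop)
            st_less = L.neighbour_positivity(0, adj, grades)
            assert st_less.pct_positive_neighbours >= st_full.pct_positive_neighbours


class TestRankComparison:
    def test_identical_groups_give_p_one(self):
        gc = L.rank_compare([50.0, 50.0, 50.0], [50.0, 50.0, 50.0])
        assert gc.p_value == 1.0
        assert gc.group_means == (50.0, 50.0)

    def test_complete_separation_exact_enumeration(self):
        """3 vs 3 complete separation: 2 of the C(6,3)=20 assignments are as
        extreme, so the exact two-sided p is 0.1 (verified by enumeration)."""
        gc = L.rank_compare([100.0, 100.0, 100.0], [0.0, 0.0, 0.0])
        assert gc.test_name == "mann-whitney-exact"
        assert gc.p_value == pytest.approx(0.1)
        # independent enumeration oracle over the 20 assignments
        from scipy.stats import rankdata

        pooled = np.array([100.0, 100.0, 100.0, 0.0, 0.0, 0.0])
        ranks = rankdata(pooled)
        u_obs = ranks[:3].sum() - 6.0
        count = sum(
            abs(ranks[list(c)].sum() - 6.0 - 4.5) >= abs(u_obs - 4.5) - 1e-9
            for c in itertools.combinations(range(6), 3)
        )
        assert gc.p_value == pytest.approx(count / 20.0)

    def test_small_groups_rejected(self):
        with pytest.raises(L.ComputationError, match="at least 3"):
            L.rank_compare([1.0, 2.0], [3.0, 4.0, 5.0])

    @given(
        st.lists(st.integers(0, 100), min_size=3, max_size=8),
        st.lists(st.integers(0, 100), min_size=3, max_size=8),
    )
    def test_symmetric_under_group_swap(self, a, b):
        x = [float(v) for v in a]
        y = [float(v) for v in b]
        g1 = L.rank_compare(x, y)
        g2 = L.rank_compare(y, x)
        assert g1.p_value == pytest.approx(g2.p_value, rel=1e-9)
        assert g1.group_means == (g2.group_means[1], g2.group_means[0])

    def test_neighbour_comparison_wrapper(self):
        pos = [
            L.NeighbourStat(i, 4, 4, 100.0) for i in range(3)
        ]
        neg = [L.NeighbourStat(10 + i, 4, 0, 0.0) for i in range(3)]
        gc = L.compare_neighbour_positivity(pos, neg)
        assert gc.group_means == (100.0, 0.0)
        assert gc.p_value == pytest.approx(0.1)

    def test_shuffled_alveolus_labels_reject_at_nominal_rate(self, default_gland):
        """Destroying the lobule structure by shuffling alveolus positivity
        makes the neighbour comparison a calibrated null.  One seed per
        lobule keeps the observations independent (seeds sharing a lobule
        share neighbours, which the pooled rank test does not model)."""
        _, pattern, alveoli, adjacency, _ = default_gland
        grades = L.grade_alveoli(pattern, alveoli)
        by_lobule = {}
        for a in alveoli:
            by_lobule.setdefault(a.lobule_id, []).append(a.id)
        idx_of = {g.alveolus_id: i for i, g in enumerate(grades)}
        rng = np.random.default_rng(123)
        flags = np.array([g.any_positive for g in grades])
        rejections = n_tests = 0
        for _ in range(100):
            rng.shuffle(flags)
            shuffled = [
                L.grade_alveolus(10 if f else 0, 20, alveolus_id=g.alveolus_id)
                for g, f in zip(grades, flags)
            ]
            seeds = [m[rng.integers(len(m))] for m in by_lobule.values()]
            seed_grades = [shuffled[idx_of[s]] for s in seeds]
            ps = L.neighbour_table(
                [g for g in seed_grades if g.any_positive], adjacency, shuffled
            )
            ns = L.neighbour_table(
                [g for g in seed_grades if not g.any_positive], adjacency, shuffled
            )
            if len(ps) < 3 or len(ns) < 3:
                continue
            n_tests += 1
            rejections += L.compare_neighbour_positivity(ps, ns).p_value < 0.05
        assert n_tests >= 80
        assert rejections <= binom.ppf(0.995, n_tests, 0.05)


class TestDimensions:
    def _alv(self, aid, major, minor):
        return L.Alveolus(
            id=aid, lobule_id=1, lumen_centre=(0.0, 0.0),
            lumen_major_axis=major, lumen_minor_axis=minor, orientation=0.0,
        )

    def test_identical_dimension_multisets_tie(self):
        pos = [self._alv(i, 30.0, 20.0) for i in range(5)]
        neg = [self._alv(10 + i, 30.0, 20.0) for i in range(5)]
        comps = L.compare_dimensions(pos, neg)
        assert comps["major"].p_value == 1.0
        assert comps["minor"].p_value == 1.0

    def test_shifted_dimensions_detected(self):
        """+50 um shift at n=50 per group rejects decisively (power frozen
        after a pilot: p < 1e-6 in every pilot replicate)."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            a = rng.normal(25, 6, 50)
            b = rng.normal(75, 6, 50)
            pos = [self._alv(i, float(v), float(v) * 0.8) for i, v in enumerate(a)]
            neg = [self._alv(100 + i, float(v), float(v) * 0.8) for i, v in enumerate(b)]
            comps = L.compare_dimensions(pos, neg)
            assert comps["major"].p_value < 1e-6
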