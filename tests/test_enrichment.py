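import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p53mutome import (GeneSet, RankedList, enrichment_score,
                       permutation_significance, rank_genes)
from p53mutome.types import EmptyInputError

from conftest import make_study


# -- independent running-sum oracle (plain python, no shortcuts) ----------
def brute_force_es(metric, hit_positions, weight):
    n = len(metric)
    hits = set(hit_positions)
    in_set = [abs(metric[i]) ** weight for i in sorted(hits)]
    total = sum(in_set)
    running, best = 0.0, 0.0
    for i in range(n):
        if i in hits:
            running += (abs(metric[i]) ** weight / total) if total > 0 \
                else 1.0 / len(hits)
        else:
            running -= 1.0 / (n - len(hits))
        if abs(running) > abs(best):
            best = running
    return best


def _ranked4():
    return RankedList(genes=np.array(["a", "b", "c", "d"]),
                      metric=np.array([3.0, 2.0, 1.0, 0.5]))


class TestRankGenes:
    def test_descending_order_forced(self):
        study = make_study({"null": [1, 1, 1, 1],
                            "WT": [15, 7, 3, 1.8],
                            "M": [1, 1, 1, 1]})
        ranked = rank_genes(study, "WT", "null")
        assert list(ranked.genes) == ["g000", "g001", "g002", "g003"]
        assert all(x >= y for x, y in zip(ranked.metric, ranked.metric[1:]))

    def test_identical_conditions_tie_break_is_lexicographic(self):
        study = make_study({"null": [5, 5, 5], "WT": [5, 5, 5],
                            "M": [5, 5, 5]})
        ranked = rank_genes(study, "WT", "null")
        assert np.allclose(ranked.metric, 0.0)
        assert list(ranked.genes) == sorted(ranked.genes)

    def test_row_permutation_invariance(self):
        study = make_study({"null": [1, 5, 2], "WT": [9, 2, 4],
                            "M": [1, 1, 1]})
        shuffled = make_study({"null": [2, 1, 5], "WT": [4, 9, 2],
                               "M": [1, 1, 1]})
        shuffled.matrix.index = ["g002", "g000", "g001"]
        a = rank_genes(study, "WT", "null")
        b = rank_genes(shuffled, "WT", "null")
        assert list(a.genes) == list(b.genes)
        assert np.allclose(a.metric, b.metric)

    def test_same_condition_contrast_rejected(self):
        study = make_study({"null": [1], "WT": [2], "M": [1]})
        with pytest.raises(ValueError):
            rank_genes(study, "WT", "WT")

    def test_s2n_metric_available(self):
        study = make_study({"null": [2, 30], "WT": [30, 2], "M": [1, 1]},
                           jitter=0.1, seed=3)
        ranked = rank_genes(study, "WT", "null", metric="s2n")
        assert ranked.metric[0] > 0 > ranked.metric[-1]


class TestEnrichmentScore:
    def test_top_pair_unweighted_reaches_one(self):
        es, run = enrichment_score(_ranked4(), {"a", "b"}, weight=0)
        assert es == 1.0
        assert np.allclose(run, [0.5, 1.0, 0.5, 0.0])

    def test_bottom_pair_is_minus_one(self):
        es, _ = enrichment_score(_ranked4(), {"c", "d"}, weight=0)
        assert es == -1.0

    @pytest.mark.parametrize("weight", [0.0, 1.0, 2.0])
    def test_singleton_at_top_reaches_one(self, weight):
        es, _ = enrichment_score(_ranked4(), {"a"}, weight=weight)
        assert es == 1.0

    def test_running_sum_ends_at_zero(self):
        _, run = enrichment_score(_ranked4(), {"b", "d"}, weight=1)
        assert run[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            metric = np.round(rng.normal(size=n), 3)
            genes = np.array([f"g{i:02d}" for i in range(n)])
            ranked = RankedList(genes=genes, metric=metric)
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, k, replace=False))
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            es, _ = enrichment_score(ranked, members, weight)
            pos = [i for i, g in enumerate(ranked.genes) if g in members]
            assert es == pytest.approx(
                brute_force_es(ranked.metric, pos, weight), abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_es_bounded_by_one(self, data):
        n = data.draw(st.integers(4, 25))
        metric = np.array(data.draw(st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n)))
        genes = np.array([f"g{i:02d}" for i in range(n)])
        k = data.draw(st.integers(1, n - 1))
        members = set(genes[:k])
        es, _ = enrichment_score(RankedList(genes=genes, metric=metric),
                                 members, weight=1.0)
        assert -1.0 <= es <= 1.0 + 1e-12

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(23)
        metric = np.sort(rng.normal(size=12))[::-1]
        genes = np.array([f"g{i:02d}" for i in range(12)])
        members = set(rng.choice(genes, 4, replace=False))
        es, _ = enrichment_score(RankedList(genes=genes, metric=metric),
                                 members, weight=0.0)
        rev = RankedList(genes=genes[::-1].copy(), metric=-metric[::-1].copy())
        es_rev, _ = enrichment_score(rev, members, weight=0.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_reversal_negates_weighted_es_on_symmetric_profile(self):
        metric = np.array([3.0, 1.0, 0.5, -0.5, -1.0, -3.0])
        genes = np.array(list("abcdef"))
        members = {"a", "c", "e"}
        es, _ = enrichment_score(RankedList(genes=genes, metric=metric),
                                 members, weight=1.0)
        rev = RankedList(genes=genes[::-1].copy(), metric=-metric[::-1].copy())
        es_rev, _ = enrichment_score(rev, members, weight=1.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_full_coverage_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(_ranked4(), {"a", "b", "c", "d"})

    def test_no_overlap_rejected(self):
        with pytest.raises(EmptyInputError):
            enrichment_score(_ranked4(), {"x"})


class TestPermutationSignificance:
    def test_exhaustive_p_on_six_assignment_fixture(self):
        res = permutation_significance(
            _ranked4(), [GeneSet("top", frozenset({"a", "b"}))],
            n_perm=50, seed=1)[0]
        assert res.method == "exhaustive"
        assert res.n_null == 6
        assert res.p_nominal == pytest.approx(1 / 6)

    def test_identical_set_twice_gives_identical_results(self):
        rng = np.random.default_rng(2)
        genes = np.array([f"g{i:03d}" for i in range(60)])
        ranked = RankedList(genes=genes, metric=rng.normal(size=60))
        gs = GeneSet("s", frozenset(genes[:8]))
        a = permutation_significance(ranked, [gs], n_perm=100, seed=5,
                                     exhaustive_limit=0)
        b = permutation_significance(ranked, [gs], n_perm=100, seed=5,
                                     exhaustive_limit=0)
        assert a[0].to_dict() == b[0].to_dict()

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            permutation_significance(_ranked4(), [GeneSet("t", frozenset("a"))],
                                     n_perm=10)

    def test_montecarlo_matches_exhaustive_conditional_p(self):
        # same-sign-conditional tail probability, both routes
        rng = np.random.default_rng(9)
        n, k = 9, 3
        metric = rng.normal(size=n)
        genes = np.array([f"g{i}" for i in range(n)])
        ranked = RankedList(genes=genes, metric=metric)
        members = frozenset(rng.choice(genes, k, replace=False))
        obs, _ = enrichment_score(ranked, members, weight=1.0)
        null = []
        for pos in itertools.combinations(range(n), k):
            null.append(brute_force_es(ranked.metric, pos, 1.0))
        null = np.array(null)
        if obs >= 0:
            cond_p = (null[null >= 0] >= obs).sum() / (null >= 0).sum()
        else:
            cond_p = (null[null < 0] <= obs).sum() / (null < 0).sum()
        res = permutation_significance(ranked, [GeneSet("s", members)],
                                       n_perm=4000, seed=3,
                                       exhaustive_limit=0)[0]
        assert res.method == "permutation"
        # binomial error at n_perm = 4000
        assert res.p_nominal == pytest.approx(cond_p, abs=0.03)

    def test_planted_signal_is_significant_and_positive(self):
        rng = np.random.default_rng(31)
        n = 300
        metric = rng.normal(0, 0.2, n)
        members = rng.choice(n, 25, replace=False)
        metric[members] += 1.5
        genes = np.array([f"g{i:03d}" for i in range(n)])
        ranked = RankedList(genes=genes, metric=metric)
        gs = GeneSet("planted", frozenset(genes[members]))
        res = permutation_significance(ranked, [gs], n_perm=500, seed=11)[0]
        assert res.es > 0
        assert res.nes > 1
        assert res.p_nominal < 0.01
        assert res.fdr_q < 0.25 and res.significant

    def test_fdr_q_within_bounds_for_many_sets(self):
        rng = np.random.default_rng(13)
        n = 120
        genes = np.array([f"g{i:03d}" for i in range(n)])
        ranked = RankedList(genes=genes, metric=rng.normal(size=n))
        sets = [GeneSet(f"s{j}", frozenset(rng.choice(genes, 10, replace=False)))
                for j in range(8)]
        results = permutation_significance(ranked, sets, n_perm=200, seed=7,
                                           exhaustive_limit=0)
        for r in results:
            assert 0.0 <= r.fdr_q <= 1.0
            assert 0.0 < r.p_nominal <= 1.0
            assert r.significant == (r.fdr_q < 0.25)
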