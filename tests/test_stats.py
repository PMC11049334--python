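import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multidiff import (
    aupr,
    auroc,
    benjamini_hochberg,
    enrich_gene_sets,
    evaluate_known_positives,
    hypergeom_upper_tail,
    overlap_test,
)
from multidiff.scoring import ScoreTable


def enumerate_upper_tail(k, n, K, N):
    """Brute-force P(X >= k): enumerate all C(N, n) draws from the universe."""
    universe = range(N)
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_worked_example(self):
        # C(5,3)C(5,1) + C(5,4)C(5,0) over C(10,4) = 55/210
        assert hypergeom_upper_tail(3, 4, 5, 10) == pytest.approx(55 / 210, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        assert hypergeom_upper_tail(0, 4, 5, 10) == 1.0

    def test_full_universe_draw_forces_full_overlap(self):
        assert hypergeom_upper_tail(3, 10, 3, 10) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(4, 10, 3, 10)

    def test_matches_enumeration_on_full_grid(self):
        for N in range(1, 13):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(n, K) + 1):
                        expected = enumerate_upper_tail(k, n, K, N)
                        assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
                            expected, abs=1e-12
                        ), (k, n, K, N)

    def test_matches_scipy_cross_check(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(5)
        for _ in range(200):
            N = int(rng.integers(5, 2000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expected = float(hypergeom.sf(k - 1, N, K, n))
            assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
                expected, rel=1e-9, abs=1e-300
            )

    def test_parameter_violations_raise(self):
        for bad in [(1, 0, 5, 10), (1, 4, 0, 10), (1, 11, 5, 10), (-1, 4, 5, 10), (5, 4, 5, 10)]:
            with pytest.raises(ValueError):
                hypergeom_upper_tail(*bad)


class TestOverlapTest:
    def test_disjoint_sets(self):
        universe = {f"P{i}" for i in range(20)}
        ot = overlap_test({"P1", "P2"}, {"P5", "P6"}, universe)
        assert ot.k == 0 and ot.p_value == 1.0

    def test_subset_overlap_is_extreme(self):
        universe = {f"P{i}" for i in range(30)}
        disease = {f"P{i}" for i in range(10)}
        ot = overlap_test({"P1", "P2", "P3"}, disease, universe)
        assert ot.k == ot.n == 3
        # minimum attainable p for n=3 given these K, N
        assert ot.p_value == pytest.approx(
            hypergeom_upper_tail(3, 3, 10, 30), abs=1e-15
        )

    def test_pvalues_superuniform_under_permuted_disease(self):
        # under a random disease set the upper-tail p is super-uniform:
        # P(p <= u) <= u for every u
        rng = np.random.default_rng(11)
        universe = [f"P{i}" for i in range(60)]
        targets = set(universe[:8])
        pvals = []
        for _ in range(1000):
            disease = set(rng.choice(universe, size=12, replace=False))
            pvals.append(overlap_test(targets, disease, set(universe)).p_value)
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        # allow small-sample slack on the empirical CDF
        assert np.all(ecdf - pvals <= 0.05)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test({"a"}, {"b"}, set())


class TestEnrichment:
    def test_bh_step_up_hand_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_bh_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=40)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_identical_set_achieves_minimum_p(self):
        universe = {f"P{i}" for i in range(40)}
        targets = {f"P{i}" for i in range(6)}
        rows = enrich_gene_sets(targets, {"own": set(targets)}, universe)
        assert rows[0].overlap == 6
        assert rows[0].p_value == pytest.approx(
            hypergeom_upper_tail(6, 6, 6, 40), abs=1e-15
        )

    def test_no_overlap_gives_p_one(self):
        universe = {f"P{i}" for i in range(40)}
        rows = enrich_gene_sets(
            {"P0", "P1"}, {"far": {"P30", "P31"}, "away": {"P20"}}, universe
        )
        assert all(r.p_value == 1.0 for r in rows)

    def test_outside_universe_set_skipped(self, caplog):
        universe = {f"P{i}" for i in range(10)}
        rows = enrich_gene_sets({"P0"}, {"alien": {"XX"}, "ok": {"P0", "P1"}}, universe)
        assert [r.set_name for r in rows] == ["ok"]


class TestAurocAupr:
    def test_printed_toy_cases(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        labels = [1, 0, 1, 0]
        assert auroc(scores, labels) == pytest.approx(0.75)
        assert aupr(scores, labels) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert auroc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0
        assert aupr([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5
        assert aupr([1, 1, 1, 1], [1, 0, 1, 0]) == pytest.approx(0.5)  # prevalence

    def test_pairwise_concordance_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            scores = rng.choice(10, size=n).astype(float)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auroc(scores, labels) == pytest.approx(conc / (len(pos) * len(neg)))

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        for i in range(100):
            n = int(rng.integers(4, 60))
            tie = i % 2 == 0
            scores = rng.choice(8, size=n).astype(float) if tie else rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-9
            )
            assert aupr(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-9
            )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-30, 30), min_size=4, max_size=30), st.data())
    def test_monotone_transform_invariance(self, scores, data):
        # integer scores keep exp() injective in floating point, so the
        # transform is strictly monotone and preserves every tie exactly
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if sum(labels) in (0, len(labels)):
            return
        base = auroc([float(s) for s in scores], labels)
        transformed = auroc([math.exp(0.3 * s) for s in scores], labels)
        assert transformed == pytest.approx(base, abs=1e-9)

    def test_score_negation_complements_auroc(self, rng):
        scores = rng.normal(size=25)  # continuous, tie-free a.s.
        labels = (rng.random(25) < 0.4).astype(int)
        labels[0], labels[1] = 1, 0
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)

    def test_random_scores_aupr_near_prevalence(self):
        rng = np.random.default_rng(3)
        n, n_pos = 200, 50
        labels = np.zeros(n, int)
        labels[:n_pos] = 1
        vals = []
        for _ in range(1000):
            vals.append(aupr(rng.normal(size=n), labels))
        assert np.mean(vals) == pytest.approx(n_pos / n, abs=0.04)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            aupr([1, 2, 3], [0, 0, 0])


class TestEvaluateKnownPositives:
    def _table(self, ids, scores):
        df = pd.DataFrame({"compound_id": ids, "name": ids, "score": scores})
        df["n_targets_in_network"] = 3
        df["rank"] = range(1, len(df) + 1)
        return ScoreTable(table=df)

    def test_positives_on_top_give_perfect_auroc(self):
        st_ = self._table(list("abcdef"), [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        ev = evaluate_known_positives(st_, {"a", "b", "c"})
        assert ev.auroc == 1.0 and ev.aupr == 1.0
        assert ev.n_positive == 3 and ev.n_total == 6

    def test_random_placement_near_chance(self):
        rng = np.random.default_rng(9)
        ids = [f"c{i}" for i in range(60)]
        vals = []
        for _ in range(300):
            scores = rng.normal(size=60)
            pos = set(rng.choice(ids, size=10, replace=False))
            df = self._table(ids, scores)
            vals.append(evaluate_known_positives(df, pos).auroc)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_missing_positives_rejected(self):
        st_ = self._table(["a", "b"], [0.2, 0.1])
        with pytest.raises(ValueError, match="no known positive"):
            evaluate_known_positives(st_, {"zz"})

    def test_curve_points_span_unit_ranges(self):
        st_ = self._table(list("abcdef"), [0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        ev = evaluate_known_positives(st_, {"a", "d"})
        assert ev.roc_points["fpr"].iloc[-1] == 1.0
        assert ev.roc_points["tpr"].iloc[-1] == 1.0
        assert ev.pr_points["recall"].iloc[-1] == 1.0
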