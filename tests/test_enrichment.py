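from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from resistm import (
    SyntheticCohortConfig,
    assign_risk,
    build_heatmap_table,
    compare_scores_by_subtype,
    enrichment_test,
    score_reflected_median,
    simulate_cohort,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(x, y):
    """Enumerate every assignment of the pooled (tie-free) observations
    to groups; two-sided p = 2 * min tail of the U distribution."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum()
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= obs_u).mean(), (us >= obs_u).mean())
    return min(p, 1.0)


class TestWilcoxon:
    def test_two_vs_two_extreme_configuration(self):
        # all of x below all of y: one of the two most extreme of the
        # C(4,2)=6 assignments, exact two-sided p = 2/6
        _, p, method = wilcoxon_rank_sum([1, 2], [3, 4])
        assert method == "exact"
        assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p, _ = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1", range(1, 7))
    @pytest.mark.parametrize("n2", range(1, 7))
    def test_exact_p_equals_enumeration_for_all_small_sizes(self, n1, n2):
        rng = np.random.default_rng(97 * n1 + n2)
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
        _, p, method = wilcoxon_rank_sum(x, y)
        assert method == "exact"
        assert p == pytest.approx(exact_rank_sum_p(x, y), rel=1e-12)

    def test_normal_approximation_close_to_enumeration(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10)
        x[3] = x[7]  # one tie forces the asymptotic path
        y = rng.normal(0.5, 1, 10)
        _, p_approx, method = wilcoxon_rank_sum(x, y)
        assert method == "asymptotic"
        # enumeration oracle with midranks over all C(20,10) assignments
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled)
        obs = ranks[:10].sum()
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, 10)), dtype=float
        )
        p_enum = min(1.0, 2 * min((sums <= obs + 1e-9).mean(),
                                  (sums >= obs - 1e-9).mean()))
        assert abs(p_approx - p_enum) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


class TestSubtypeComparisons:
    def test_planted_shift_detected_in_cms4_vs_rest(self, demo_cohort, registry):
        sv = score_reflected_median(demo_cohort.expression, registry["RESIST-M"])
        with pytest.warns(UserWarning, match="without a cms label"):
            table = compare_scores_by_subtype(sv, demo_cohort.clinical)
        rest = table[table["group_b"] == "rest"].iloc[0]
        # reflected-median polarity: risk-enriched CMS4 scores LOWER
        assert rest["direction"] == "lower"
        assert rest["p_value"] < 0.01
        assert {"CMS1", "CMS2", "CMS3"} <= set(table["group_b"])
        assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()

    def test_null_rejection_rate_is_nominal(self, registry):
        sig = registry["RESIST-M"]
        rejections = 0
        n_reps = 100
        for i in range(n_reps):
            cohort = simulate_cohort(SyntheticCohortConfig(
                n_samples=200, seed=5_000 + i, m1_shift=0.0, m2_shift=0.0,
                planted_hr=1.0))
            sv = score_reflected_median(cohort.expression, sig)
            with pytest.warns(UserWarning):
                table = compare_scores_by_subtype(sv, cohort.clinical)
            rejections += table[table["group_b"] == "rest"]["p_value"].iloc[0] < 0.05
        assert 0.0 <= rejections / n_reps <= 0.11

    def test_single_subtype_rejected(self, registry):
        cohort = simulate_cohort(SyntheticCohortConfig(
            n_samples=30, seed=1, subtype_proportions={"CMS2": 1.0}))
        sv = score_reflected_median(cohort.expression, registry["RESIST-M"])
        with pytest.raises(ValueError, match="two groups"):
            compare_scores_by_subtype(sv, cohort.clinical)


class TestHeatmap:
    def test_shape_zscore_and_column_order(self, demo_cohort, registry):
        table = build_heatmap_table(demo_cohort.expression, registry,
                                    demo_cohort.clinical)
        n_sig_genes = len({g for name in ("RESIST-M", "Lin", "Yin", "RCC7", "RPS")
                           for g in registry[name].genes})
        assert table.matrix.shape == (n_sig_genes, demo_cohort.expression.shape[1])
        vals = table.matrix.to_numpy()
        np.testing.assert_allclose(vals.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(vals.std(axis=1, ddof=1), 1.0, atol=1e-12)
        # column order is a permutation of the sample ids
        assert sorted(table.matrix.columns) == sorted(demo_cohort.expression.columns)
        # CMS annotation is non-decreasing along the configured order
        codes = table.annotations["cms"].cat.codes.to_numpy()
        assert (np.diff(codes) >= 0).all()
        # block structure covers the five signatures in fixed order
        blocks = [table.blocks[g] for g in table.matrix.index]
        seen = list(dict.fromkeys(blocks))
        assert seen == ["RESIST-M", "Lin", "Yin", "RCC7", "RPS"]

    def test_long_format_row_count(self, demo_cohort, registry):
        table = build_heatmap_table(demo_cohort.expression, registry,
                                    demo_cohort.clinical)
        long = table.to_long()
        assert len(long) == table.matrix.size
        assert {"gene", "signature_block", "sample_id", "zscore", "cms"} <= set(
            long.columns)


class TestEnrichment:
    @staticmethod
    def _frame(status, target):
        n = len(status)
        clin = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "cms": np.where(target, "CMS4", "CMS2"),
            "fibrosis": np.where(target, "fibrotic", "non-fibrotic"),
        })
        return pd.Series(status, index=clin["sample_id"].to_numpy()), clin

    def test_independence_table(self):
        status, clin = self._frame([1] * 10 + [0] * 10,
                                   ([True] * 5 + [False] * 5) * 2)
        res = enrichment_test(status, clin)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.table.tolist() == [[5, 5], [5, 5]]

    def test_perfect_association_hypergeometric_p(self):
        status, clin = self._frame([1] * 10 + [0] * 10,
                                   [True] * 10 + [False] * 10)
        res = enrichment_test(status, clin)
        assert np.isinf(res.odds_ratio)
        assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_transpose_symmetry_of_fisher_p(self):
        from scipy.stats import fisher_exact

        table = np.array([[7, 3], [2, 9]])
        _, p = fisher_exact(table)
        _, pt = fisher_exact(table.T)
        assert p == pytest.approx(pt, rel=1e-12)

    def test_empty_target_class_rejected(self):
        status, clin = self._frame([1, 0, 1, 0], [False] * 4)
        with pytest.raises(ValueError, match="empty"):
            enrichment_test(status, clin)

    def test_planted_cohort_strongly_enriched(self, demo_cohort, registry):
        risk = assign_risk(score_reflected_median(demo_cohort.expression,
                                                  registry["RESIST-M"]))
        res = enrichment_test(risk, demo_cohort.clinical)
        assert res.odds_ratio > 5
        assert res.p_value < 1e-6
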