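import math

import numpy as np
import pytest

from nodemri.errors import DataError
from nodemri.stats import (
    DEFAULT_PRE_MODEL,
    ComparisonResult,
    GroupSummary,
    PreModel,
    chisq_2x2,
    diagnostic_metrics,
    fit_pre_model,
    icc_two_observers,
    paired_compare,
    pooled_t_from_summary,
    pre_score,
    roc_analysis,
    two_group_compare,
)


class TestPooledT:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [
            ((76.85, 12.89, 52), (30.99, 17.55, 42), 14.60),
            ((2.95, 3.05, 52), (6.60, 6.74, 42), -3.49),
            ((263.71, 68.44, 52), (205.60, 56.83, 42), 4.41),
            ((1226.75, 385.23, 52), (925.81, 311.04, 42), 4.10),
        ],
    )
    def test_reproduces_published_group_contrasts(self, g1, g2, expected):
        t = pooled_t_from_summary(GroupSummary(*g1), GroupSummary(*g2))
        assert round(t, 2) == expected

    def test_equal_means_give_zero(self):
        assert pooled_t_from_summary(GroupSummary(5, 1, 10), GroupSummary(5, 2, 12)) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(DataError):
            GroupSummary(5, 1, 1)

    def test_matches_raw_sample_t(self, rng):
        """Summary-based t equals the pooled t computed from raw samples
        having exactly those summaries."""
        a = rng.normal(10, 2, 40)
        b = rng.normal(11, 3, 35)
        res = two_group_compare(a, b)
        assert res.test_name == "pooled t"
        t = pooled_t_from_summary(
            GroupSummary(a.mean(), a.std(ddof=1), a.size),
            GroupSummary(b.mean(), b.std(ddof=1), b.size),
        )
        assert res.statistic == pytest.approx(t, rel=1e-12)


class TestChiSquare:
    def test_reproduces_published_regimen_table(self):
        res = chisq_2x2(42, 10, 30, 12)
        assert round(res.statistic, 2) == 1.13

    def test_proportional_rows_give_zero(self):
        assert chisq_2x2(20, 10, 40, 20).statistic == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_closed_form(self):
        assert chisq_2x2(10, 0, 0, 10).statistic == pytest.approx(20.0)

    def test_pearson_formula_oracle(self):
        a, b, c, d = 13, 7, 5, 11
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chisq_2x2(a, b, c, d).statistic == pytest.approx(expected, rel=1e-12)

    def test_fisher_and_yates_modes(self):
        fisher = chisq_2x2(2, 8, 7, 3, correction="fisher")
        assert fisher.test_name == "fisher exact"
        assert 0 <= fisher.p_value <= 1
        yates = chisq_2x2(42, 10, 30, 12, correction="yates")
        assert yates.statistic < chisq_2x2(42, 10, 30, 12).statistic

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            chisq_2x2(0, 0, 5, 5)


class TestPreScore:
    def test_published_coefficients_at_cutoffs(self):
        assert pre_score(222.0, 934.0) == pytest.approx(0.5085, abs=5e-5)
        assert pre_score(0.0, 0.0) == pytest.approx(0.00349, abs=5e-6)

    def test_monotone_in_both_inputs(self):
        base = pre_score(200.0, 900.0)
        assert pre_score(201.0, 900.0) > base
        assert pre_score(200.0, 901.0) > base

    def test_vectorized(self):
        out = pre_score(np.array([0.0, 222.0]), np.array([0.0, 934.0]))
        assert out.shape == (2,)


class TestFitPreModel:
    def test_recovers_generating_coefficients(self, rng):
        n = 5000
        pf = rng.uniform(100, 420, n)
        kt = rng.uniform(300, 2000, n)
        p = pre_score(pf, kt, DEFAULT_PRE_MODEL)
        labels = np.where(rng.uniform(size=n) < p, "RG", "NRG")
        model = fit_pre_model(pf, kt, labels)
        assert model.converged
        assert model.intercept == pytest.approx(-5.654, rel=0.15)
        assert model.coef_pf == pytest.approx(0.013, rel=0.15)
        assert model.coef_ktrans == pytest.approx(0.003, rel=0.15)

    def test_null_model_has_small_coefficients(self, rng):
        n = 4000
        pf = rng.uniform(100, 400, n)
        kt = rng.uniform(300, 2000, n)
        labels = np.where(rng.uniform(size=n) < 0.5, "RG", "NRG")
        model = fit_pre_model(pf, kt, labels)
        # ~3 standard errors of the null MLE at this design and n
        assert abs(model.coef_pf) < 1.5e-3
        assert abs(model.coef_ktrans) < 2.5e-4

    def test_duplicating_the_dataset_changes_nothing(self, rng):
        pf = rng.uniform(100, 400, 60)
        kt = rng.uniform(300, 2000, 60)
        labels = ["RG" if v > 250 else "NRG" for v in pf * 0.5 + kt * 0.1]
        m1 = fit_pre_model(pf, kt, labels)
        m2 = fit_pre_model(np.tile(pf, 2), np.tile(kt, 2), labels * 2)
        assert m1.intercept == pytest.approx(m2.intercept, rel=1e-5)
        assert m1.coef_pf == pytest.approx(m2.coef_pf, rel=1e-5)

    def test_perfect_separation_is_flagged(self):
        pf = np.array([1.0] * 10 + [100.0] * 10)
        kt = np.zeros(20)
        labels = ["NRG"] * 10 + ["RG"] * 10
        model = fit_pre_model(pf, kt, labels)
        assert not model.converged


def _brute_force_auc(pos, neg):
    """Exhaustive concordant-pair count with half-credit for ties."""
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in pos for y in neg)
    return wins / (len(pos) * len(neg))


class TestRocAnalysis:
    def test_perfect_separation(self):
        perf = roc_analysis([1, 2, 3, 10, 11, 12], ["NRG"] * 3 + ["RG"] * 3)
        assert perf.auc == 1.0
        assert perf.youden == pytest.approx(1.0)

    def test_toy_set_matches_pair_counting_oracle(self):
        scores = [3.0, 1.0, 2.0, 2.0, 5.0, 4.0]
        labels = ["RG", "NRG", "NRG", "RG", "RG", "NRG"]
        pos = [s for s, l in zip(scores, labels) if l == "RG"]
        neg = [s for s, l in zip(scores, labels) if l == "NRG"]
        perf = roc_analysis(scores, labels)
        assert perf.auc == pytest.approx(_brute_force_auc(pos, neg), abs=1e-15)

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=120)
        y = rng.integers(0, 2, size=120)
        labels = ["RG" if v else "NRG" for v in y]
        perf = roc_analysis(scores, labels)
        assert perf.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_null_auc_near_half(self, rng):
        scores = rng.normal(size=400)
        labels = ["RG" if v < 0.5 else "NRG" for v in rng.uniform(size=400)]
        perf = roc_analysis(scores, labels)
        se = 3 * np.sqrt(0.25 / 100)
        assert abs(perf.auc - 0.5) < se

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=80)
        labels = ["RG" if v > 0 else "NRG" for v in scores + rng.normal(0, 2, 80)]
        p1 = roc_analysis(scores, labels)
        p2 = roc_analysis(np.exp(3 * scores), labels)
        assert p1.auc == pytest.approx(p2.auc, abs=1e-12)
        assert p1.youden == pytest.approx(p2.youden, abs=1e-12)

    def test_youden_cutoff_is_exhaustive_argmax(self, rng):
        for _ in range(20):
            scores = np.round(rng.normal(size=30), 1)  # ties on purpose
            labels = ["RG" if v > 0 else "NRG" for v in scores + rng.normal(0, 1.5, 30)]
            if len(set(labels)) < 2:
                continue
            pos = np.array([s for s, l in zip(scores, labels) if l == "RG"])
            neg = np.array([s for s, l in zip(scores, labels) if l == "NRG"])
            best_j = max(
                float(np.mean(pos >= thr) + np.mean(neg < thr) - 1.0)
                for thr in np.unique(scores)
            )
            perf = roc_analysis(scores, labels)
            assert perf.youden == pytest.approx(best_j, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_analysis([1, 2, 3], ["RG", "RG", "RG"])

    def test_delong_ci_brackets_auc(self, rng):
        scores = rng.normal(size=90)
        labels = ["RG" if v > -0.2 else "NRG" for v in scores + rng.normal(0, 1, 90)]
        perf = roc_analysis(scores, labels)
        lo, hi = perf.auc_ci_95
        assert lo <= perf.auc <= hi
        assert 0.0 <= lo and hi <= 1.0


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "sens,spec,youden,lr_pos,lr_neg,ppv,npv",
        [
            # printed sensitivities/specificities reconstructed as exact counts
            (36 / 52, 36 / 42, 0.549, 4.85, 0.36, 85.7, 69.2),
            (39 / 52, 27 / 42, 0.393, 2.10, 0.39, 72.2, 67.5),
            (36 / 52, 27 / 42, 0.335, 1.94, 0.48, 70.6, 62.8),
        ],
    )
    def test_reproduces_published_diagnostic_rows(
        self, sens, spec, youden, lr_pos, lr_neg, ppv, npv
    ):
        d = diagnostic_metrics(sens, spec, 52, 42)
        assert round(d.youden, 3) == youden
        assert round(d.lr_pos, 2) == lr_pos
        assert round(d.lr_neg, 2) == lr_neg
        assert round(d.ppv, 1) == ppv
        assert round(d.npv, 1) == npv

    def test_perfect_test(self):
        d = diagnostic_metrics(1.0, 1.0, 10, 10)
        assert d.youden == 1.0
        assert d.ppv == 100.0 and d.npv == 100.0
        assert math.isinf(d.lr_pos)

    def test_consistent_with_integer_confusion_matrix(self):
        tp, fn, fp, tn = 36, 16, 6, 36
        d = diagnostic_metrics(tp / (tp + fn), tn / (tn + fp), tp + fn, tn + fp)
        assert d.ppv == pytest.approx(100 * tp / (tp + fp), abs=1e-9)
        assert d.npv == pytest.approx(100 * tn / (tn + fn), abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            diagnostic_metrics(1.2, 0.5, 10, 10)
        with pytest.raises(DataError):
            diagnostic_metrics(0.5, 0.5, 0, 10)


class TestPairedCompare:
    def test_detects_constant_shift(self, rng):
        pre = rng.normal(10, 1, 40)
        post = pre + 1.0 + rng.normal(0, 0.01, 40)
        res = paired_compare(pre, post)
        assert res.p_value < 1e-3
        assert res.statistic < 0  # post > pre in the pre-minus-post convention

    def test_identical_series(self):
        x = np.arange(10.0)
        res = paired_compare(x, x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_switches_to_wilcoxon_for_skewed_differences(self, rng):
        pre = rng.normal(10, 1, 60)
        post = pre + rng.lognormal(0, 1.5, 60)  # heavily skewed paired diffs
        res = paired_compare(pre, post)
        assert "wilcoxon" in res.test_name

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            paired_compare([1, 2, 3], [1, 2])


class TestTwoGroupCompare:
    def test_identical_constant_groups(self):
        res = two_group_compare([5.0] * 5, [5.0] * 6)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_separated_normals(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        res = two_group_compare(a, b)
        assert res.p_value < 1e-6

    def test_mann_whitney_for_nonnormal(self, rng):
        a = rng.lognormal(0, 2.0, 60)
        b = rng.lognormal(0.5, 2.0, 60)
        res = two_group_compare(a, b)
        assert res.test_name == "mann-whitney U"


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.5, 3.0, 4.2, 7.7])
        assert icc_two_observers(x, x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        x1 = rng.normal(size=10_000)
        x2 = rng.normal(size=10_000)
        assert abs(icc_two_observers(x1, x2)) < 0.05

    def test_matches_pingouin_two_way_random_single(self, rng):
        import pandas as pd
        import pingouin as pg

        x1 = rng.normal(10, 3, 12)
        x2 = x1 + rng.normal(0.5, 1.0, 12)
        ours = icc_two_observers(x1, x2)
        df = pd.DataFrame(
            {
                "subject": list(range(12)) * 2,
                "rater": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([x1, x2]),
            }
        )
        icc_table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ref = float(icc_table.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_zero_between_subject_variance_flagged(self):
        with pytest.warns(UserWarning):
            out = icc_two_observers([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert math.isnan(out)
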