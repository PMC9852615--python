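"""Diagnostic statistics: correlation, ROC, cut-offs, ICC, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from femcort.diagstats import (
    ConfusionMatrix,
    ReconstructionError,
    StatisticsError,
    auc_brute_force,
    compare_groups,
    confusion_at_cutoff,
    diagnostic_summary,
    icc,
    pearson,
    predictive_values,
    reconstruct_confusion,
    roc,
    summary_ttest,
    table3_report,
    youden_cutoff,
)


class TestPearson:
    def test_perfect_positive(self, rng):
        x = rng.normal(size=50)
        assert pearson(x, x).r == pytest.approx(1.0)

    def test_perfect_negative_affine(self, rng):
        x = rng.normal(size=50)
        assert pearson(x, -2 * x + 5).r == pytest.approx(-1.0)

    def test_recovers_planted_correlation(self, rng):
        rho = 0.475
        n = 200_000
        z = rng.standard_normal((n, 2))
        y = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
        assert pearson(z[:, 0], y).r == pytest.approx(rho, abs=0.01)

    def test_constant_input_rejected(self):
        with pytest.raises(StatisticsError):
            pearson(np.ones(10), np.arange(10.0))

    def test_too_short_rejected(self):
        with pytest.raises(StatisticsError):
            pearson(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


class TestROC:
    def test_perfect_separation(self):
        s = np.r_[np.zeros(20), np.ones(20)]
        lab = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        assert roc(s, lab).auc == pytest.approx(1.0)

    def test_null_auc_is_half(self, rng):
        s = rng.normal(size=50_000)
        lab = rng.random(50_000) < 0.5
        assert roc(s, lab).auc == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(40, 500)
        # discrete scores force ties so the half-count convention matters
        s = rng.integers(0, 12, n).astype(float)
        lab = rng.random(n) < 0.4
        if lab.all() or not lab.any():
            lab[0] = ~lab[0]
        for orient in ("higher", "lower"):
            assert roc(s, lab, orient).auc == pytest.approx(
                auc_brute_force(s, lab, orient), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=400)
        lab = rng.random(400) < 0.5
        a1 = roc(s, lab).auc
        assert roc(np.exp(s), lab).auc == pytest.approx(a1, abs=1e-12)
        assert roc(np.argsort(np.argsort(s)).astype(float), lab).auc == \
            pytest.approx(a1, abs=1e-12)

    def test_ci_clipped_to_unit_interval(self):
        s = np.r_[np.zeros(15), np.ones(15)]
        lab = np.r_[np.zeros(15, bool), np.ones(15, bool)]
        lo, hi = roc(s, lab).ci
        assert 0.0 <= lo <= hi <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(StatisticsError):
            roc(np.arange(5.0), np.ones(5, bool))

    def test_binormal_auc_recovered(self, rng):
        from scipy.stats import norm

        target = 0.883
        d = np.sqrt(2.0) * norm.ppf(target)
        s = np.r_[rng.normal(d, 1.0, 100_000), rng.normal(0.0, 1.0, 100_000)]
        lab = np.r_[np.ones(100_000, bool), np.zeros(100_000, bool)]
        assert roc(s, lab).auc == pytest.approx(target, abs=0.01)


class TestYouden:
    def test_equals_exhaustive_threshold_scan(self, rng):
        s = rng.normal(size=500)
        lab = rng.random(500) < 0.5
        r = roc(s, lab)
        cutoff, se, sp = youden_cutoff(r)
        # oracle: scan every candidate midpoint cutoff directly
        uniq = np.unique(s)
        mids = (uniq[:-1] + uniq[1:]) / 2
        best = -np.inf
        for c in mids:
            pred = s > c
            jse = np.sum(pred & lab) / lab.sum()
            jsp = np.sum(~pred & ~lab) / (~lab).sum()
            best = max(best, jse + jsp - 1)
        assert se + sp - 1 == pytest.approx(best, abs=1e-12)

    def test_separated_classes_cutoff_inside_gap(self):
        s = np.r_[np.linspace(0, 1, 20), np.linspace(2, 3, 20)]
        lab = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        cutoff, se, sp = youden_cutoff(roc(s, lab, "lower"))
        assert 1.0 < cutoff < 2.0
        assert se == sp == 1.0

    def test_symmetric_gaussians_recover_planted_midpoint(self):
        rng = np.random.default_rng(13)
        osteo = rng.normal(3.185 - 0.8, 0.84, 100_000)
        healthy = rng.normal(3.185 + 0.8, 0.84, 100_000)
        s = np.r_[osteo, healthy]
        lab = np.r_[np.ones(100_000, bool), np.zeros(100_000, bool)]
        cutoff, _, _ = youden_cutoff(roc(s, lab, "lower"))
        assert cutoff == pytest.approx(3.185, abs=0.02)


class TestConfusion:
    def test_printed_row_one_predictive_values(self):
        pv = predictive_values(ConfusionMatrix(tp=21, fp=9, fn=4, tn=22))
        assert round(pv.ppv, 3) == 0.700
        assert round(pv.npv, 3) == 0.846
        assert round(pv.se, 2) == 0.84
        assert round(pv.sp, 2) == 0.71

    def test_printed_row_two_predictive_values(self):
        pv = predictive_values(ConfusionMatrix(tp=19, fp=4, fn=6, tn=27))
        assert round(pv.ppv, 3) == 0.826
        assert round(pv.npv, 3) == 0.818

    def test_perfect_classifier(self):
        pv = predictive_values(ConfusionMatrix(tp=10, fp=0, fn=0, tn=12))
        assert pv.se == pv.sp == pv.ppv == pv.npv == 1.0
        assert pv.accuracy == 1.0

    def test_zero_denominator_flagged_not_fabricated(self):
        pv = predictive_values(ConfusionMatrix(tp=0, fp=0, fn=5, tn=10))
        assert pv.ppv is None and "ppv" in pv.undefined

    def test_negative_counts_rejected(self):
        with pytest.raises(StatisticsError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=2)

    @given(tp=st.integers(0, 40), fp=st.integers(0, 40),
           fn=st.integers(0, 40), tn=st.integers(1, 40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ratios_bounded_and_accuracy_consistent(self, tp, fp, fn, tn):
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        pv = predictive_values(cm)
        for v in (pv.se, pv.sp, pv.ppv, pv.npv):
            assert v is None or 0.0 <= v <= 1.0
        assert pv.accuracy == pytest.approx((tp + tn) / cm.total)


class TestReconstruction:
    def test_unique_table_for_row_one(self):
        cm = reconstruct_confusion(56, 0.84, 0.71, ("npv", 0.846))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (21, 9, 4, 22)

    def test_unique_table_for_row_two(self):
        cm = reconstruct_confusion(56, 0.76, 0.871, ("ppv", 0.826))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (19, 4, 6, 27)

    def test_no_auxiliary_constraint_is_ambiguous(self):
        with pytest.raises(ReconstructionError) as exc:
            reconstruct_confusion(56, 0.84, 0.71)
        assert len(exc.value.candidates) >= 2
        quads = {(c.tp, c.fp, c.fn, c.tn) for c in exc.value.candidates}
        assert (21, 9, 4, 22) in quads

    def test_reconstruction_reproduces_all_printed_fractions(self):
        # the held-out predictive value also rounds to its printed value
        cm = reconstruct_confusion(56, 0.84, 0.71, ("npv", 0.846))
        pv = predictive_values(cm)
        assert round(pv.ppv, 1) == 0.7
        cm2 = reconstruct_confusion(56, 0.76, 0.871, ("ppv", 0.826))
        assert round(predictive_values(cm2).npv, 3) == 0.818


class TestICC:
    def test_identical_raters_give_unity(self, rng):
        col = rng.normal(size=(50, 1))
        assert icc(np.repeat(col, 3, axis=1)).value == pytest.approx(1.0)

    def test_independent_raters_give_zero(self, rng):
        X = rng.normal(size=(10_000, 3))
        assert icc(X).value == pytest.approx(0.0, abs=0.02)

    def test_variance_components_closed_form(self, rng):
        # subject variance 4, error variance 1 -> ICC = 4/5 = 0.8
        subj = rng.normal(0.0, 2.0, size=(10_000, 1))
        X = subj + rng.normal(0.0, 1.0, size=(10_000, 3))
        assert icc(X).value == pytest.approx(0.8, abs=0.02)

    def test_matches_pingouin_absolute_agreement(self, rng):
        pg = pytest.importorskip("pingouin")
        X = rng.normal(0.0, 2.0, size=(40, 1)) + rng.normal(size=(40, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(40), 3),
            "rater": np.tile(np.arange(3), 40),
            "score": X.ravel()})
        ref = pg.intraclass_corr(long, "subject", "rater", "score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(ref["Type"]) \
            else ref[ref["Type"] == "ICC2"].iloc[0]
        ours = icc(X)
        assert ours.value == pytest.approx(float(row["ICC"]), abs=1e-9)

    def test_two_exchangeable_raters_match_pearson(self, rng):
        subj = rng.normal(0.0, 1.0, size=(20_000, 1))
        X = subj + rng.normal(0.0, 1.0, size=(20_000, 2))
        r = pearson(X[:, 0], X[:, 1]).r
        assert icc(X).value == pytest.approx(r, abs=0.02)

    def test_zero_between_subject_variance_flagged(self):
        X = np.ones((10, 3))
        assert icc(X).degenerate

    def test_too_few_subjects_rejected(self):
        with pytest.raises(StatisticsError):
            icc(np.ones((3, 3)))


class TestGroupComparisons:
    def test_identical_groups_null_statistic(self, rng):
        vals = rng.normal(size=40)
        df = pd.DataFrame({"v": np.r_[vals, vals]})
        mask = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        res = compare_groups(df, mask, ["v"])[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_printed_age_contrast_from_summary_stats(self):
        res = summary_ttest(76.48, 10.22, 180, 79.04, 8.50, 195, variable="age")
        assert res.p == pytest.approx(0.009, abs=0.002)

    def test_proportional_rows_give_zero_chi_square(self):
        x = np.array(["a"] * 30 + ["b"] * 60)
        y = np.array(["a"] * 10 + ["b"] * 20)
        df = pd.DataFrame({"v": np.r_[x, y]})
        mask = np.r_[np.ones(90, bool), np.zeros(30, bool)]
        res = compare_groups(df, mask, [("v", "categorical")])[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_fisher_selected_for_sparse_tables(self):
        x = np.array(["a"] * 2 + ["b"] * 30)
        y = np.array(["a"] * 8 + ["b"] * 10)
        df = pd.DataFrame({"v": np.r_[x, y]})
        mask = np.r_[np.ones(32, bool), np.zeros(18, bool)]
        res = compare_groups(df, mask, [("v", "categorical")])[0]
        assert res.method == "fisher"

    def test_swapping_groups_flips_t_sign_keeps_p(self, rng):
        df = pd.DataFrame({"v": np.r_[rng.normal(0, 1, 50), rng.normal(0.5, 1, 60)]})
        mask = np.r_[np.ones(50, bool), np.zeros(60, bool)]
        a = compare_groups(df, mask, ["v"])[0]
        b = compare_groups(df, ~mask, ["v"])[0]
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("seed", range(4))
    def test_p_values_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 60, 2)
        df = pd.DataFrame({"v": rng.normal(size=n1 + n2),
                           "c": rng.choice(["x", "y", "z"], n1 + n2)})
        mask = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
        for method in ("welch", "student", "ranksum", "auto"):
            for res in compare_groups(df, mask, ["v", ("c", "categorical")],
                                      continuous=method):
                assert 0.0 <= res.p <= 1.0

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"v": np.arange(5.0)})
        with pytest.raises(StatisticsError):
            compare_groups(df, np.ones(5, bool), ["v"])


class TestDiagnosticSummary:
    def test_parameter_equal_to_truth_scores_auc_one(self):
        t = np.linspace(-5, 0, 56)
        cohort = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(56)],
            "osteoporotic_dxa": pd.array(t < -2.5, dtype="boolean"),
            "cth_roi21": t + 10.0,  # strictly monotone in T
            "hu_roi14": np.full(56, 500.0) + t,
        })
        rows = table3_report(cohort)
        assert len(rows) == 2
        assert rows[0].auc == pytest.approx(1.0)

    def test_calibrated_auc_recovered_on_average_at_study_scale(self):
        from scipy.stats import norm

        target = 0.883
        d = np.sqrt(2.0) * norm.ppf(target)
        rng = np.random.default_rng(99)
        aucs = []
        for _ in range(500):
            s = np.r_[rng.normal(-d, 1.0, 25), rng.normal(0.0, 1.0, 31)]
            lab = np.r_[np.ones(25, bool), np.zeros(31, bool)]
            aucs.append(roc(s, lab, "lower").auc)
        assert np.mean(aucs) == pytest.approx(target, abs=0.03)

    def test_summary_row_rounding(self, rng):
        s = np.r_[rng.normal(3.0, 0.8, 100), rng.normal(4.0, 0.8, 100)]
        lab = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        row = diagnostic_summary(s, lab, "cth_roi21")
        d = row.rounded()
        assert d["auc"] == round(row.auc, 3)
        assert set(d) >= {"auc", "ci_low", "ci_high", "cutoff", "se", "sp",
                          "ppv", "npv"}

    def test_confusion_at_cutoff_counts(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        lab = np.array([True, True, False, False])
        cm = confusion_at_cutoff(s, lab, 2.5, orientation="lower")
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 0, 0, 2)
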