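"""Centile-threshold panel construction, scoring, and ROC evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pniexpr.containers import ExpressionMatrix
from pniexpr.panel import (
    build_panel,
    centile_threshold,
    classify,
    confusion_metrics,
    mann_whitney_auc,
    null_score_calibration,
    roc_curve,
    score_samples,
)
from pniexpr.simulate import GeneratorConfig, generate_null_samples

from conftest import endogenous_only, make_matrix


def simple_panel(n_genes=3, thresholds=(5.0, 5.0, 5.0)):
    from pniexpr.panel import ScorePanel

    genes = [f"g{i + 1}" for i in range(n_genes)]
    return ScorePanel(genes=genes,
                      thresholds=pd.Series(thresholds, index=genes),
                      training_samples=["t1", "t2"])


class TestCentile:
    def test_type7_interpolated_order_statistic(self):
        assert centile_threshold(np.arange(1, 21), 0.95) == pytest.approx(19.05)

    def test_median_special_case(self):
        assert centile_threshold([1.0, 2.0, 3.0], 0.5) == 2.0


class TestBuildPanel:
    def test_genes_are_top_rows_in_order(self, main_deg_table, normalized_cohort):
        norm, _, annotation, _ = normalized_cohort
        endo = endogenous_only(norm)
        panel = build_panel(main_deg_table, endo, annotation, panel_size=10)
        assert panel.genes == list(main_deg_table.index[:10])
        assert panel.size == 10
        assert len(panel.training_samples) == 20

    def test_thresholds_are_training_95th_centiles(self, main_deg_table,
                                                   normalized_cohort):
        norm, _, annotation, _ = normalized_cohort
        endo = endogenous_only(norm)
        panel = build_panel(main_deg_table, endo, annotation)
        train = endo.values[panel.training_samples]
        for g in panel.genes:
            expected = np.quantile(train.loc[g], 0.95, method="linear")
            assert panel.thresholds[g] == pytest.approx(expected)
            # threshold lies at or above the 19th-smallest of 20 values
            assert panel.thresholds[g] >= np.sort(train.loc[g])[18]

    def test_exactly_one_of_twenty_training_values_exceeds(self, main_deg_table,
                                                           normalized_cohort):
        """Type-7 interpolation on n=20 puts the threshold between the two
        largest values, so exactly the maximum exceeds it."""
        norm, _, annotation, _ = normalized_cohort
        endo = endogenous_only(norm)
        panel = build_panel(main_deg_table, endo, annotation)
        train = endo.values[panel.training_samples]
        exceed = train.loc[panel.genes].gt(panel.thresholds, axis=0).sum(axis=1)
        assert (exceed == 1).all()

    def test_too_few_genes_rejected(self, normalized_cohort):
        norm, _, annotation, _ = normalized_cohort
        table = pd.DataFrame({"log2fc": [1.0]}, index=[norm.probe_ids[0]])
        with pytest.raises(ValueError, match="panel needs"):
            build_panel(table, endogenous_only(norm), annotation, panel_size=10)


class TestScoring:
    def test_extremes_and_strict_inequality(self):
        panel = simple_panel()
        m = make_matrix([[10.0, 1.0, 5.0],
                         [10.0, 1.0, 5.0],
                         [10.0, 1.0, 5.0]], sample_ids=["hi", "lo", "at"])
        result = score_samples(panel, m)
        assert result.totals["hi"] == 3
        assert result.totals["lo"] == 0
        # value exactly at the threshold scores 0 (strictly greater required)
        assert result.totals["at"] == 0

    def test_missing_gene_named_in_error(self):
        panel = simple_panel()
        m = make_matrix([[1.0]], probe_ids=["g1"])
        with pytest.raises(ValueError, match="g2"):
            score_samples(panel, m)

    def test_score_invariant_under_monotone_transform(self, main_deg_table,
                                                      normalized_cohort):
        norm, _, annotation, _ = normalized_cohort
        endo = endogenous_only(norm)
        panel = build_panel(main_deg_table, endo, annotation)
        base = score_samples(panel, endo).totals
        # same pipeline on log-transformed values
        logged = endo.with_values(np.log2(endo.values + 1.0))
        panel_log = build_panel(main_deg_table, logged, annotation)
        again = score_samples(panel_log, logged).totals
        pd.testing.assert_series_equal(base, again)

    def test_raising_centile_never_raises_scores(self, main_deg_table,
                                                 normalized_cohort):
        norm, _, annotation, _ = normalized_cohort
        endo = endogenous_only(norm)
        lo = build_panel(main_deg_table, endo, annotation, centile=0.90)
        hi = build_panel(main_deg_table, endo, annotation, centile=0.99)
        s_lo = score_samples(lo, endo).totals
        s_hi = score_samples(hi, endo).totals
        assert (s_hi <= s_lo).all()

    def test_classification_cutoffs(self):
        panel = simple_panel()
        totals = pd.Series([3, 2, 0], index=["a", "b", "c"])
        from pniexpr.panel import ScoreResult

        result = ScoreResult(indicators=pd.DataFrame(), totals=totals)
        pred = classify(result, 2.5)
        assert pred.to_dict() == {"a": True, "b": False, "c": False}
        assert not classify(result, 10).any()


class TestConfusionMetrics:
    def test_reported_fractions(self):
        truth = pd.Series([True] * 25 + [False] * 20)
        pred = truth.copy()
        pred.iloc[0] = False  # one false negative among 25 EXT
        pred.iloc[30] = True  # one false positive among 20 controls
        pred.iloc[31] = True
        m = confusion_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(0.96)
        assert m["specificity"] == pytest.approx(0.90)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (24, 1, 18, 2)

    def test_perfect_prediction(self):
        truth = pd.Series([True, False, True])
        m = confusion_metrics(truth.copy(), truth)
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "ppv", "npv"))

    def test_empty_class_undefined_with_warning(self):
        truth = pd.Series([True, True])
        with pytest.warns(UserWarning, match="specificity undefined"):
            m = confusion_metrics(pd.Series([True, False]), truth)
        assert m["specificity"] is None


class TestRoc:
    def test_separated_scores_auc_one(self):
        scores = pd.Series([5, 6, 7, 1, 2], index=list("abcde"))
        truth = pd.Series([True, True, True, False, False], index=list("abcde"))
        assert roc_curve(scores, truth).auc == 1.0

    def test_pure_ties_auc_half(self):
        scores = pd.Series([3.0] * 6)
        truth = pd.Series([True, False] * 3)
        assert roc_curve(scores, truth).auc == pytest.approx(0.5)

    def test_monotone_operating_points(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.integers(0, 11, 40).astype(float))
        truth = pd.Series(rng.random(40) < 0.5)
        if truth.all() or not truth.any():
            truth.iloc[0] = not truth.iloc[0]
        roc = roc_curve(scores, truth)
        assert (np.diff(roc.cutoffs) < 0).all()
        assert (np.diff(roc.sensitivity) >= 0).all()
        assert (np.diff(roc.specificity) <= 0).all()

    @given(st.integers(0, 2**32 - 1))
    def test_trapezoid_auc_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = pd.Series(rng.integers(0, 11, n).astype(float))
        truth = pd.Series(rng.random(n) < 0.4)
        if truth.all() or not truth.any():
            truth.iloc[0] = not truth.iloc[0]
        roc = roc_curve(scores, truth)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(pd.Series([1.0, 2.0]), pd.Series([True, True]))


class TestNullCalibration:
    def test_held_out_exceedance_near_nominal_with_large_training(self,
                                                                  main_deg_table):
        """With a large training set the learned 95th centile converges to the
        population centile, so held-out null samples exceed it at ~5%."""
        config = GeneratorConfig(seed=2)
        nulls = generate_null_samples(config, 2000)
        train = nulls.subset_samples(nulls.sample_ids[:1000])
        held_out = nulls.subset_samples(nulls.sample_ids[1000:])
        ann = pd.DataFrame({"cohort": "NON"}, index=train.sample_ids)
        genes = [g for g in main_deg_table.index[:10]]
        table = main_deg_table.loc[genes]
        panel = build_panel(table, endogenous_only(train), ann)
        summary = null_score_calibration(panel, endogenous_only(held_out))
        assert summary["mean_exceedance"] == pytest.approx(0.05, abs=0.01)
        assert summary["mean_score"] == pytest.approx(0.5, abs=0.1)
        assert summary["n_samples"] == 1000
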