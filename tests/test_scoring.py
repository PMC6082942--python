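"""Composite scores, ROC/AUC, operating-point diagnostics, table audit."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import arthrasight as a
from arthrasight.scoring import (
    CompositeModel,
    component_matrix,
    composite_score,
    confusion_from_rounded,
    enrich_model,
    metrics_at_cut,
    metrics_from_counts,
    roc,
    round_half_up,
)
from conftest import make_labelled


def auc_pair_counting(scores, labels):
    """Independent AUC oracle: concordant pairs + half ties over all
    event x non-event pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestCompositeScore:
    def test_all_negative_scores_zero(self, labelled_cohort):
        df = labelled_cohort.df.copy()
        for c in ("s5", "s10", "s11"):
            df[c] = 0.0
        model = CompositeModel(("s5", "s10", "s11"))
        assert (composite_score(df, model) == 0).all()

    def test_counting(self):
        df = pd.DataFrame({"s5": [1.0], "s10": [1.0], "s11": [0.0]})
        assert composite_score(df, CompositeModel(("s5", "s10", "s11")))[0] == 2

    def test_six_component_count(self):
        df = pd.DataFrame(
            {"s5": [1.0], "s10": [1.0], "s11": [0.0], "survivin_pos": [True],
             "any_ab": [True], "female_over_50": [False]}
        )
        model = CompositeModel(("s5", "s10", "s11", "survivin_pos", "any_ab", "female_over_50"))
        assert composite_score(df, model)[0] == 4

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown component"):
            CompositeModel(("s5", "bogus"))

    def test_duplicate_components_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CompositeModel(("s5", "s5"))

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"s5": [np.nan]})
        with pytest.raises(ValueError, match="missing"):
            composite_score(df, CompositeModel(("s5",)))


class TestRoc:
    def test_perfect_separation(self):
        curve = roc([3, 3, 1, 0], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_tied_example_pair_counting(self):
        curve = roc([2, 1, 1, 0], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(0.875, abs=1e-12)

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 6, 4000)
        y = rng.random(4000) < 0.2
        curve = roc(s, y)
        n1, n0 = y.sum(), (~y).sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(curve.auc - 0.5) < 3 * se
        assert curve.auc_p > 0.01

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        curve = roc(rng.integers(0, 7, 300), rng.random(300) < 0.3)
        assert curve.tpr[0] == curve.fpr[0] == 0.0
        assert curve.tpr[-1] == curve.fpr[-1] == 1.0
        assert (np.diff(curve.tpr) >= 0).all()
        assert (np.diff(curve.fpr) >= 0).all()
        assert 0.0 <= curve.auc_ci[0] <= curve.auc <= curve.auc_ci[1] <= 1.0

    def test_auc_equals_pair_counting_fuzz(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(4, 60)
            s = rng.integers(0, rng.integers(2, 8), n)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            assert roc(s, y).auc == pytest.approx(auc_pair_counting(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2, 3], [1, 1, 1])


class TestMetricsAtCut:
    def test_cut_zero_everyone_positive(self):
        m = metrics_at_cut([0, 1, 2, 3], [0, 0, 1, 1], cut=0)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0

    def test_cut_above_max_nobody_positive(self):
        m = metrics_at_cut([0, 1, 2, 3], [0, 0, 1, 1], cut=4)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0

    def test_three_clinical_operating_point(self):
        m = metrics_from_counts(tp=7, fn=25, fp=11, tn=137)
        assert round_half_up(100 * m.sensitivity, 1) == 21.9
        assert round_half_up(100 * m.specificity, 1) == 92.6
        assert round_half_up(100 * m.ppv, 1) == 38.9

    def test_cut_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="cut"):
            metrics_at_cut([0, 1, 2], [0, 1, 0], cut=9)

    def test_monotone_threshold_property(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 7, 500)
        y = rng.random(500) < 0.25
        sens, spec = [], []
        for cut in range(0, 8):
            m = metrics_at_cut(s, y, cut)
            sens.append(m.sensitivity)
            spec.append(m.specificity)
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()

    @given(k=st.integers(0, 50), n=st.integers(1, 50))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_wilson_interval_contains_point(self, k, n):
        k = min(k, n)
        from arthrasight.scoring import _prop_ci

        lo, hi = _prop_ci(k, n, "wilson")
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    @given(k=st.integers(0, 30), n=st.integers(1, 30))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_midp_interval_within_clopper_pearson(self, k, n):
        from scipy import stats
        from arthrasight.scoring import _midp_binom_ci

        k = min(k, n)
        lo, hi = _midp_binom_ci(k, n)
        cp_lo, cp_hi = stats.beta.ppf(0.025, k, n - k + 1), stats.beta.ppf(0.975, k + 1, n - k)
        cp_lo = 0.0 if k == 0 else cp_lo
        cp_hi = 1.0 if k == n else cp_hi
        assert cp_lo - 1e-9 <= lo <= k / n + 1e-12
        assert k / n - 1e-12 <= hi <= cp_hi + 1e-9


class TestConfusionAudit:
    def test_unique_reconstruction_of_printed_row(self):
        res = confusion_from_rounded(21.9, 92.6, 32, 148)
        assert res["unique"]
        sol = res["solutions"][0]
        assert sol == {"tp": 7, "fn": 25, "fp": 11, "tn": 137}

    def test_perfect_percentages(self):
        res = confusion_from_rounded(100.0, 100.0, 10, 10)
        assert res["unique"]
        assert res["solutions"][0]["tp"] == 10
        assert res["solutions"][0]["tn"] == 10

    def test_infeasible_flagged(self):
        res = confusion_from_rounded(50.0, 50.0, 3, 3)
        assert not res["feasible"]
        assert res["solutions"] == []

    @given(
        tp=st.integers(0, 40), fn=st.integers(0, 40),
        fp=st.integers(0, 40), tn=st.integers(0, 40),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_roundtrip_soundness(self, tp, fn, fp, tn):
        # auditing a rounded operating point always recovers the true counts
        if tp + fn == 0 or fp + tn == 0:
            return
        sens = round_half_up(100 * tp / (tp + fn), 1)
        spec = round_half_up(100 * tn / (fp + tn), 1)
        res = confusion_from_rounded(sens, spec, tp + fn, fp + tn)
        assert res["feasible"]
        assert {"tp": tp, "fn": fn, "fp": fp, "tn": tn} in res["solutions"]


class TestEnrichModel:
    def test_row_order_and_labels(self, labelled_cohort):
        base = CompositeModel(("s5", "s10", "s11"), name="3 clinical")
        table = enrich_model(base, labelled_cohort)
        assert list(table["model"])[:2] == ["3 clinical", "+ Survivin+CRP"]
        assert len(table) == 6
        assert list(table["n_components"]) == [3, 5, 5, 5, 6, 6]

    def test_enrichment_gains_auc_on_calibrated_cohort(self):
        cohort = make_labelled(seed=9, scale=20)
        base = CompositeModel(("s5", "s10", "s11"), name="3 clinical")
        table = enrich_model(base, cohort)
        assert (table["auc"].iloc[1:] >= table["auc"].iloc[0] - 0.02).all()
        assert (table["sens"].iloc[1:] > table["sens"].iloc[0]).all()

    def test_null_markers_leave_auc_unchanged(self):
        # markers independent of progression: enrichment adds only noise
        cfg = a.default_config(seed=31)
        prev = {m: (v[0], v[0], v[2], v[3]) for m, v in cfg.marker_prev.items()}
        cfg = replace(cfg, marker_prev=prev, missing_rate=0.0,
                      age_mean=(47.0, 47.0, 51.0, 56.0)).scaled(10)
        cohort = a.label_pre_ra(a.generate_cohort(cfg))
        from arthrasight.cohort import add_binary_markers

        cohort.df = add_binary_markers(cohort.df)
        base = CompositeModel(("s5", "s10", "s11"), name="3 clinical")
        table = enrich_model(base, cohort)
        assert (abs(table["auc"].iloc[1:] - table["auc"].iloc[0]) < 0.06).all()

    def test_majority_vote_pooling(self, labelled_cohort):
        df = labelled_cohort.df.head(4)
        comps = [np.zeros((4, 13)), np.ones((4, 13)), np.ones((4, 13))]
        values = component_matrix(df, comps)
        assert (values["s5"] == 1.0).all()
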