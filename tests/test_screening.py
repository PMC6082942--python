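"""2x2 tables, odds ratios and the OR > 2 symptom screening rule."""

from dataclasses import replace
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import arthrasight as a
from arthrasight.cohort import add_binary_markers
from arthrasight.screening import (
    TwoByTwo,
    biomarker_adherence,
    odds_ratio,
    screen_symptoms,
    two_by_two,
)
from conftest import make_labelled


class TestTwoByTwo:
    def test_perfect_agreement(self):
        t = two_by_two([1, 1, 0, 0], [1, 1, 0, 0])
        assert (t.a, t.b, t.c, t.d) == (2, 0, 0, 2)

    def test_smoker_table_orientation(self):
        # smoker counts, arthralgia (45/180) vs RA (25/63): with exposure =
        # smoker and outcome = RA, a = smoking RA cases (25), b = smoking
        # arthralgia (45), c = non-smoking RA (38), d = 135; the OR is the
        # same cross-product (25*135)/(38*45) either way round
        exposure = [1] * 25 + [0] * 38 + [1] * 45 + [0] * 135
        outcome = [1] * 63 + [0] * 180
        t = two_by_two(exposure, outcome)
        assert (t.a, t.b, t.c, t.d) == (25, 45, 38, 135)
        assert odds_ratio(t).or_hat == pytest.approx(25 * 135 / (38 * 45), abs=1e-9)

    def test_all_zero_outcome(self):
        t = two_by_two([1, 0, 1], [0, 0, 0])
        assert (t.a, t.c) == (0, 0)
        assert t.b + t.d == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            two_by_two([1, 0], [1, 0, 1])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            two_by_two([1.0, np.nan], [1.0, 0.0])


class TestOddsRatio:
    def test_symmetric_table_or_one(self):
        assert odds_ratio(TwoByTwo(2, 2, 2, 2)).or_hat == pytest.approx(1.0)

    def test_cross_product(self):
        r = odds_ratio(TwoByTwo(25, 38, 45, 135))
        assert r.or_hat == pytest.approx(25 * 135 / (38 * 45), abs=1e-4)
        assert not r.continuity_corrected

    def test_haldane_correction_on_zero_cell(self):
        r = odds_ratio(TwoByTwo(1, 0, 1, 1))
        assert r.continuity_corrected
        assert r.or_hat == pytest.approx((1.5 * 1.5) / (0.5 * 1.5))

    @given(
        a=st.integers(1, 40), b=st.integers(1, 40),
        c=st.integers(1, 40), d=st.integers(1, 40),
    )
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_transpose_and_label_swap_invariance(self, a, b, c, d):
        base = odds_ratio(TwoByTwo(a, b, c, d))
        transposed = odds_ratio(TwoByTwo(a, c, b, d))  # exposure <-> outcome
        swapped = odds_ratio(TwoByTwo(c, d, a, b))  # exposure labels flipped
        assert transposed.or_hat == pytest.approx(base.or_hat, abs=1e-12)
        assert swapped.or_hat == pytest.approx(1 / base.or_hat, rel=1e-12)

    def test_ci_brackets_estimate(self):
        r = odds_ratio(TwoByTwo(12, 7, 5, 20))
        assert r.ci_low <= r.or_hat <= r.ci_high

    def test_woolf_against_reference_small_tables(self):
        # independent oracle: statsmodels Table2x2 (log-OR normal CI) and
        # scipy's uncorrected chi-square, over all tables with cells 1..5
        import statsmodels.api as sm

        for a_, b_, c_, d_ in product(range(1, 6), repeat=4):
            mine = odds_ratio(TwoByTwo(a_, b_, c_, d_))
            tab = sm.stats.Table2x2([[a_, b_], [c_, d_]])
            lo, hi = tab.oddsratio_confint(0.05)
            assert mine.or_hat == pytest.approx(tab.oddsratio, abs=1e-10)
            assert mine.ci_low == pytest.approx(lo, abs=1e-10)
            assert mine.ci_high == pytest.approx(hi, abs=1e-10)
            chi2, p, _, _ = stats.chi2_contingency(
                [[a_, b_], [c_, d_]], correction=False
            )
            assert mine.p_value == pytest.approx(p, abs=1e-10)

    def test_midp_ci_within_conditional_exact(self):
        # mid-P exact bounds are strictly inside the conditional exact
        # (Fisher) interval; scipy's conditional exact CI is the oracle
        for cells in [(12, 7, 5, 20), (3, 9, 8, 4), (25, 38, 45, 135)]:
            t = TwoByTwo(*cells)
            mine = odds_ratio(t, method="midp_exact")
            res = stats.contingency.odds_ratio(
                [[t.a, t.b], [t.c, t.d]], kind="conditional"
            )
            lo, hi = res.confidence_interval(0.95)
            assert lo < mine.ci_low < mine.ci_high < hi

    @pytest.mark.parametrize("p_method", ["pearson", "yates", "fisher", "midp"])
    def test_p_value_methods_agree_in_order(self, p_method):
        # Yates and Fisher are conservative relative to Pearson on 2x2s
        t = TwoByTwo(12, 7, 5, 20)
        p = odds_ratio(t, p_method=p_method).p_value
        assert 0 < p < 1
        if p_method in ("yates", "fisher"):
            assert p >= odds_ratio(t, p_method="pearson").p_value


class TestScreenSymptoms:
    def test_selected_items_at_scale(self):
        cohort = make_labelled(seed=101, scale=20)
        assert screen_symptoms(cohort).selected == [5, 10, 11]

    def test_infinite_threshold_selects_nothing(self, labelled_cohort):
        assert screen_symptoms(labelled_cohort, threshold=np.inf).selected == []

    def test_unlabelled_cohort_rejected(self, labelled_cohort):
        cohort = a.Cohort(labelled_cohort.df.drop(columns=["group"]))
        with pytest.raises(ValueError, match="label"):
            screen_symptoms(cohort)

    def test_frame_has_counts_and_flags(self, labelled_cohort):
        frame = screen_symptoms(labelled_cohort).to_frame()
        assert len(frame) == 13
        assert (frame[["a", "b", "c", "d"]].sum(axis=1) == 180).all()
        assert frame["selected"].equals(frame["or"] > 2.0)

    def test_null_false_selection_rate(self):
        # with no symptom-outcome association, the OR>2 rule selects on
        # average fewer than 2 of 13 items at the study's sample size
        prev = a.default_config().symptom_prev.copy()
        prev[:, 1] = prev[:, 0]  # pre-RA equals remaining arthralgia
        n_sel = []
        for seed in range(100):
            cfg = replace(a.default_config(seed=seed), symptom_prev=prev, missing_rate=0.0)
            n_sel.append(len(screen_symptoms(make_null_cohort(cfg)).selected))
        assert np.mean(n_sel) < 2


def make_null_cohort(cfg):
    cohort = a.label_pre_ra(a.generate_cohort(cfg))
    cohort.df = add_binary_markers(cohort.df)
    return cohort


class TestBiomarkerAdherence:
    def test_group_sizes_reported(self, labelled_cohort):
        table = biomarker_adherence(labelled_cohort, "survivin_pos")
        assert len(table) == 13
        assert (table["n_pos"] + table["n_neg"] == 180).all()

    def test_configured_association_detected_at_scale(self):
        # survivin multiplies the odds of items 1,2,5,6,8,10,13 by 2.5; at
        # 20x size their CIs should exclude 1
        cohort = make_labelled(seed=55, scale=20)
        table = biomarker_adherence(cohort, "survivin_pos").set_index("symptom")
        for item in (1, 2, 5, 6, 8, 10, 13):
            assert table.loc[item, "ci_low"] > 1, item

    def test_null_marker_cis_cover_one(self):
        cfg = replace(a.default_config(seed=77), assoc_or={}, missing_rate=0.0).scaled(5)
        cohort = a.label_pre_ra(a.generate_cohort(cfg))
        cohort.df = add_binary_markers(cohort.df)
        table = biomarker_adherence(cohort, "survivin_pos")
        covers = ((table["ci_low"] <= 1) & (table["ci_high"] >= 1)).sum()
        assert covers >= 11

    def test_monomorphic_marker_rejected(self, labelled_cohort):
        df = labelled_cohort.df.copy()
        df["survivin_pos"] = True
        with pytest.raises(ValueError, match="monomorphic"):
            biomarker_adherence(a.Cohort(df), "survivin_pos")

    def test_unknown_marker_rejected(self, labelled_cohort):
        with pytest.raises(ValueError, match="unknown marker"):
            biomarker_adherence(labelled_cohort, "nonsense")
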