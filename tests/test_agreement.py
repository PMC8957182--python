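"""Agreement statistics against hand computations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import septostrain as st
from septostrain.errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    MissingDataError,
    UndefinedCorrelationError,
    UndefinedKappaError,
    UndefinedTestError,
)

from conftest import make_curve


def pairs(a, b, **kw):
    return st.PairedMeasurements(value_a=np.asarray(a, float), value_b=np.asarray(b, float), **kw)


class TestBlandAltman:
    def test_hand_computed_example(self):
        res = st.bland_altman(pairs([10, 8, 9], [12, 8, 7]))
        assert res.bias == pytest.approx(0.0)
        assert res.sd == pytest.approx(2.0)
        assert res.loa_low == pytest.approx(-3.92)
        assert res.loa_high == pytest.approx(3.92)

    def test_identical_columns(self):
        res = st.bland_altman(pairs([5, 6, 7], [5, 6, 7]))
        assert res.bias == 0.0 and res.sd == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_loa_width_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 40), rng.normal(10, 2, 40)
        res = st.bland_altman(pairs(a, b))
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd, abs=1e-9)

    def test_bias_changes_sign_when_columns_swapped(self):
        res_ab = st.bland_altman(pairs([10, 9, 12], [8, 9, 10]))
        res_ba = st.bland_altman(pairs([8, 9, 10], [10, 9, 12]))
        assert res_ab.bias == pytest.approx(-res_ba.bias)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            st.bland_altman(pairs([1.0], [2.0]))

    def test_incomplete_pairs_dropped(self):
        p = pairs([1, 2, np.nan, 4], [1, np.nan, 3, 4])
        assert p.n_pairs == 2 and p.n_dropped == 2


class TestICC:
    def test_perfect_agreement(self):
        res = st.icc_absolute_single(np.array([[1, 1], [2, 2], [3, 3]], float))
        assert res.icc == pytest.approx(1.0)

    def test_constant_offset_below_one_and_matches_anova(self):
        m = np.array([[1, 2], [2, 3], [3, 4]], float)
        res = st.icc_absolute_single(m)
        assert res.icc < 1.0
        # independent two-way ANOVA decomposition
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((m - m.mean(1, keepdims=True) - m.mean(0, keepdims=True) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.icc == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_on_random_matrices(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for trial in range(8):
            m = rng.normal(0, 1, (10, 2)) + rng.normal(0, 2, (10, 1))
            res = st.icc_absolute_single(m)
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(10), 2),
                    "rater": np.tile([0, 1], 10),
                    "score": m.ravel(),
                }
            )
            ref = pingouin.intraclass_corr(
                data=df, targets="subject", raters="rater", ratings="score"
            )
            ref_row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
            assert res.icc == pytest.approx(ref_row["ICC"], abs=1e-9)
            lo, hi = ref_row["CI95"]
            assert res.ci_low == pytest.approx(lo, abs=0.02)
            assert res.ci_high == pytest.approx(hi, abs=0.02)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        m = rng.normal(0, 1, (12, 3)) + rng.normal(0, 1.5, (12, 1))
        res = st.icc_absolute_single(m)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_degenerate_and_missing(self):
        with pytest.raises(DegenerateVarianceError):
            st.icc_absolute_single(np.full((4, 2), 3.0))
        m = np.array([[1, 2], [2, np.nan], [3, 4]], float)
        with pytest.raises(MissingDataError):
            st.icc_absolute_single(m)
        with pytest.raises(InsufficientDataError):
            st.icc_absolute_single(np.array([[1, 2], [2, 3]], float))

    def test_estimator_recovers_known_variance_components(self):
        # y_ij = s_i + r_j + e_ij with var 4 / 0.25 / 1:
        # target ICC = 4 / (4 + 0.25 + 1)
        rng = np.random.default_rng(123)
        target = 4.0 / 5.25
        estimates = []
        for _ in range(100):
            s = rng.normal(0, 2.0, (150, 1))
            r = rng.normal(0, 0.5, (1, 2))
            e = rng.normal(0, 1.0, (150, 2))
            estimates.append(st.icc_absolute_single(s + r + e).icc)
        assert np.mean(estimates) == pytest.approx(target, abs=0.05)


class TestKappa:
    def test_perfect_agreement(self):
        a = np.array(["x", "y", "x", "y", "y"])
        assert st.cohen_kappa(a, a.copy()) == pytest.approx(1.0)

    def test_confusion_matrix_example(self):
        # 2x2 confusion counts [[20, 5], [10, 15]] over n = 50:
        # p_o = 0.70, p_e = 0.50, kappa = 0.40
        a = ["p"] * 25 + ["n"] * 25
        b = ["p"] * 20 + ["n"] * 5 + ["p"] * 10 + ["n"] * 15
        assert st.cohen_kappa(a, b) == pytest.approx(0.40)

    def test_chance_level_agreement_gives_zero(self):
        # independent marginals constructed so p_o == p_e exactly
        a = ["p"] * 2 + ["n"] * 2
        b = ["p", "n", "p", "n"]
        assert st.cohen_kappa(a, b) == pytest.approx(0.0)

    def test_matches_sklearn_on_random_vectors(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.integers(0, 3, 40)
            b = np.where(rng.random(40) < 0.6, a, rng.integers(0, 3, 40))
            assert st.cohen_kappa(a, b) == pytest.approx(
                sklearn_metrics.cohen_kappa_score(a, b), abs=1e-12
            )

    def test_undefined_for_constant_identical_raters(self):
        with pytest.raises(UndefinedKappaError):
            st.cohen_kappa(["a", "a", "a"], ["a", "a", "a"])


class TestPairedTTest:
    def test_matches_scipy(self):
        a = np.array([10.0, 8.0, 12.0, 9.0, 11.0])
        b = np.array([8.0, 10.0, 10.0, 11.0, 9.0])
        t, p = st.paired_ttest(pairs(a, b))
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_symmetric_differences_hand_computed(self):
        d = np.array([2.0, -2.0, 2.0, -2.0, 2.0])
        t, p = st.paired_ttest(pairs(d, np.zeros(5)))
        sd = d.std(ddof=1)
        assert t == pytest.approx(d.mean() / (sd / np.sqrt(5)), abs=1e-12)

    def test_null_case(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = st.paired_ttest(pairs(a, a[::-1]))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedTestError):
            st.paired_ttest(pairs([2, 3, 4, 5], [1, 2, 3, 4]))


class TestCurveSimilarity:
    def test_self_similarity_across_resampling(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([[0], np.cumsum(rng.normal(0, 1, 89))])
        c90 = make_curve(y, frame_rate=90.0)
        c60 = c90.resampled(60)
        assert st.curve_similarity(c90, c60) == pytest.approx(1.0, abs=0.005)

    def test_negation_gives_minus_one(self):
        y = np.sin(np.linspace(0, 2 * np.pi, 50))
        a = make_curve(y)
        b = make_curve(-y)
        assert st.curve_similarity(a, b) == pytest.approx(-1.0, abs=1e-9)

    def test_amplitude_invariance_and_symmetry(self):
        pat = st.StrainPattern(family="lbbb_type", target_ss=14.0, target_srs=4.0)
        timing = st.resting_timing(70.0)
        a = st.generate_strain_curve(pat, timing, 90.0, seed=3)
        assert st.curve_similarity(a, a.scaled(2.0)) == pytest.approx(1.0, abs=1e-9)
        b = st.generate_strain_curve(pat, timing, 60.0, seed=4)
        assert st.curve_similarity(a, b) == pytest.approx(
            st.curve_similarity(b, a), abs=1e-12
        )

    def test_constant_curve_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            st.curve_similarity(make_curve(np.zeros(20)), make_curve(np.ones(20)))


class TestFeasibilityTally:
    def test_acquisition_percentage(self):
        log = pd.DataFrame(
            {
                "condition": ["all"] * 165,
                "acquired": [True] * 137 + [False] * 28,
                "attended_both_visits": [True] * 137 + [False] * 28,
                "sufficient_quality": [True] * 105 + [False] * 60,
                "grade": ["good"] * 137 + [None] * 28,
            }
        )
        out = st.feasibility_tally(log)
        overall = out[out.condition == "overall"].iloc[0]
        assert overall.n_acquired == 137
        assert overall.pct_acquired == pytest.approx(100 * 137 / 165, abs=0.05)

    def test_all_good(self):
        log = pd.DataFrame(
            {
                "condition": ["baseline"] * 4,
                "acquired": True,
                "attended_both_visits": True,
                "sufficient_quality": True,
                "grade": "good",
            }
        )
        out = st.feasibility_tally(log)
        row = out[out.condition == "baseline"].iloc[0]
        assert row.pct_acquired == 100.0
        assert row.pct_sufficient == 100.0
        assert row.pct_good == 100.0

    def test_empty_log(self):
        out = st.feasibility_tally(pd.DataFrame())
        assert out.empty
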