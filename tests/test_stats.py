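"""Statistical battery: normality gate, ANOVA/post-hoc, ROC, correlation,
paired bias, ICC(2,k), SEM/MDC, and the report builders."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cervitrace import (
    CohortSpec,
    group_anova,
    icc_2k,
    interpret_icc,
    mdc_from_sem,
    paired_bias_test,
    pearson_with_ndi,
    reliability_report,
    roc_analysis,
    sem_from_diff,
    shapiro_gate,
    simulate_cohort,
    validity_report,
)
from cervitrace.errors import (
    DegenerateSampleError,
    IncompleteMatrixError,
    InsufficientDataError,
    InvalidInputError,
    InvalidLabelsError,
    TransformInfeasibleError,
)


class TestShapiroGate:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(1).normal(size=200)
        rep = shapiro_gate(x)
        assert rep.decision == "normal" and rep.transformed is None

    def test_lognormal_sample_gated_and_fixed(self):
        x = np.random.default_rng(2).lognormal(0.0, 1.0, 200)
        rep = shapiro_gate(x)
        assert rep.decision == "ln_transformed"
        assert sps.shapiro(rep.transformed).pvalue > 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            shapiro_gate(np.ones(20))

    def test_nonpositive_values_cannot_be_transformed(self):
        x = np.random.default_rng(3).lognormal(0.0, 1.0, 100) - 5.0
        if sps.shapiro(x).pvalue < 0.05:  # gated by construction
            with pytest.raises(TransformInfeasibleError):
                shapiro_gate(x)


class TestGroupAnova:
    def test_identical_groups_no_effect(self):
        g = {"A": np.ones(10), "B": np.ones(10), "C": np.ones(10)}
        res = group_anova(g)
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
        res = group_anova({"A": a, "B": b})
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_power_at_unit_effect(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = {"A": rng.normal(0, 1, 50), "B": rng.normal(0, 1, 50),
                 "C": rng.normal(1, 1, 50)}
            if group_anova(g).p_value < 0.05:
                hits += 1
        assert hits >= 95

    def test_bonferroni_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(5)
        g = {k: rng.normal(0, 1, 20) for k in "ABC"}
        res = group_anova(g)
        for pair in res.posthoc_p:
            assert res.posthoc_p[pair] >= res.posthoc_p_raw[pair]
            assert res.posthoc_p[pair] <= 1.0

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_anova({"A": np.arange(5.0), "B": np.array([1.0])})


def auc_pair_counting(scores, labels, low_is_case=True):
    """Exhaustive case-control pair counting oracle (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    total = wins = 0.0
    for i in np.where(y)[0]:
        for j in np.where(~y)[0]:
            total += 1
            case_more_caselike = s[i] < s[j] if low_is_case else s[i] > s[j]
            wins += 1.0 if case_more_caselike else (0.5 if s[i] == s[j] else 0.0)
    return wins / total


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.ones(5), np.zeros(5)]  # cases have LOW scores
        res = roc_analysis(scores, labels, cutoff=0.5)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.one_minus_specificity == 0.0

    def test_null_case(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=1000)
        labels = np.r_[np.ones(500), np.zeros(500)]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.05)
        assert res.auc_p > 0.05

    @pytest.mark.parametrize("scores,expected", [
        ([1, 2, 3, 4], 1.0),
        ([1, 3, 2, 4], 0.75),
    ])
    def test_hand_examples(self, scores, expected):
        labels = [1, 1, 0, 0]
        assert roc_analysis(scores, labels).auc == pytest.approx(expected)

    def test_matches_pair_counting_on_random_small_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(4, 13)
            scores = rng.integers(0, 5, n).astype(float)  # ties likely
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            mine = roc_analysis(scores, labels).auc
            oracle = auc_pair_counting(scores, labels)
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        mine = roc_analysis(scores, labels, low_scores_are_cases=False).auc
        assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidLabelsError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_with_ndi(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_with_ndi(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # direct covariance / SD formula
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, p = pearson_with_ndi(x, y)
        assert r == pytest.approx(r_hand, rel=1e-12)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            pearson_with_ndi(np.ones(5), np.arange(5.0))


class TestPairedBias:
    def test_no_change_gives_t0_p1(self):
        x = np.arange(10.0)
        t, p = paired_bias_test(x, x)
        assert t == 0.0 and p == 1.0

    def test_simulated_learning_effect_detected(self):
        rng = np.random.default_rng(9)
        t1 = rng.normal(50, 10, 60)
        t2 = t1 + 1.0 + rng.normal(0, 1, 60)
        _, p = paired_bias_test(t1, t2)
        assert p < 0.001

    def test_n1_rejected(self):
        with pytest.raises(InsufficientDataError):
            paired_bias_test([1.0], [2.0])

    def test_constant_nonzero_shift_degenerate(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateSampleError):
            paired_bias_test(x, x + 3.0)


class TestIcc:
    def test_duplicated_columns_give_exactly_1(self):
        x = np.random.default_rng(10).normal(50, 10, 20)
        res = icc_2k(np.column_stack([x, x]))
        assert res.icc == 1.0
        assert res.label == "perfect"

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        true = rng.normal(50, 10, 30)
        m = np.column_stack([true + rng.normal(0, 3, 30),
                             true + 2 + rng.normal(0, 3, 30)])
        res = icc_2k(m)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile([0, 1], 30),
            "score": m.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        assert res.icc == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-6)
        lo, hi = ref.loc["ICC(A,k)", "CI95"]  # pingouin rounds CI to 2 d.p.
        assert res.ci95[0] == pytest.approx(lo, abs=0.011)
        assert res.ci95[1] == pytest.approx(hi, abs=0.011)

    def test_systematic_shift_lowers_absolute_agreement(self):
        rng = np.random.default_rng(12)
        true = rng.normal(50, 10, 40)
        m = np.column_stack([true + rng.normal(0, 2, 40),
                             true + rng.normal(0, 2, 40)])
        shifted = m.copy()
        shifted[:, 1] += 5.0
        assert icc_2k(shifted).icc < icc_2k(m).icc

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(13)
        m = rng.normal(50, 10, (25, 2))
        perm = rng.permutation(25)
        assert icc_2k(m[perm]).icc == pytest.approx(icc_2k(m).icc, rel=1e-12)

    def test_added_noise_lowers_icc(self):
        rng = np.random.default_rng(14)
        true = rng.normal(50, 10, 40)
        clean = np.column_stack([true, true + rng.normal(0, 1, 40)])
        noisy = clean.copy()
        noisy[:, 1] += rng.normal(0, 8, 40)
        assert icc_2k(noisy).icc < icc_2k(clean).icc

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(15)
        true = rng.normal(0, 10, 30)
        m = np.column_stack([true + rng.normal(0, 4, 30),
                             true + rng.normal(0, 4, 30)])
        res = icc_2k(m)
        assert -1 <= res.ci95[0] <= res.icc <= res.ci95[1] <= 1

    def test_incomplete_matrix_rejected(self):
        m = np.random.default_rng(16).normal(size=(10, 2))
        m[3, 1] = np.nan
        with pytest.raises(IncompleteMatrixError):
            icc_2k(m)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            icc_2k(np.full((10, 2), 7.0))

    def test_interpretation_bands(self):
        assert interpret_icc(0.3) == "poor"
        assert interpret_icc(0.6) == "moderate"
        assert interpret_icc(0.85) == "good"
        assert interpret_icc(0.95) == "excellent"
        assert interpret_icc(1.0) == "perfect"


class TestSemMdc:
    def test_identical_tests_zero_sem(self):
        x = np.arange(10.0)
        assert sem_from_diff(x, x) == 0.0

    def test_hand_computed_sem(self):
        # diffs {+1, -1}: SD = sqrt(2), SEM = 1
        assert sem_from_diff([0.0, 0.0], [1.0, -1.0]) == pytest.approx(1.0)

    def test_pure_systematic_bias_zero_sem(self):
        x = np.arange(6.0)
        assert sem_from_diff(x, x + 3.0) == pytest.approx(0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert sem_from_diff(a + 100, b + 100) == pytest.approx(sem_from_diff(a, b))

    def test_mdc_factor(self):
        assert mdc_from_sem(1.0) == pytest.approx(2.7719, abs=1e-4)
        assert mdc_from_sem(0.0) == 0.0
        with pytest.raises(InvalidInputError):
            mdc_from_sem(-0.1)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(seed=42))


class TestReports:

    def test_validity_report_structure(self, cohort):
        occ1 = cohort[cohort["occasion"] == 1]
        rep = validity_report(occ1)
        assert set(rep) == {"groups", "roc", "ndi_correlations"}
        assert len(rep["groups"]) == 4  # one row per outcome variable
        assert {"F", "p", "eta_squared"}.issubset(rep["groups"].columns)
        assert set(rep["roc"]["contrast"]) == {"NP_vs_CON", "INP_vs_CON", "TNP_vs_CON"}
        assert ((rep["roc"]["auc"] >= 0) & (rep["roc"]["auc"] <= 1)).all()
        assert len(rep["ndi_correlations"]) == 8  # 2 patient groups x 4 vars

    def test_roc_direction_patients_low(self, cohort):
        # generated patients have lower NormAcuity, so AUC must exceed 0.5
        occ1 = cohort[cohort["occasion"] == 1]
        rep = validity_report(occ1)
        np_row = rep["roc"].set_index("contrast").loc["NP_vs_CON"]
        assert np_row["auc"] > 0.5

    def test_reliability_report_and_duplicated_occasions(self, cohort):
        occ1 = cohort[cohort["occasion"] == 1]
        occ2 = cohort[cohort["occasion"] == 2]
        rel = reliability_report(occ1, occ2)
        assert len(rel) == 4
        assert np.allclose(rel["mdc"], rel["sem"] * 2.7719, rtol=1e-4)
        # duplicated occasions -> perfect agreement rows
        dup = reliability_report(occ1, occ1.copy())
        assert (dup["icc"] == 1.0).all()
        assert (dup["sem"] == 0.0).all()
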