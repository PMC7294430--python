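"""ROC calibration statistics: AUC, DeLong CI, Youden cut-points, grading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accelcal.roc import (
    HIGH,
    LOW,
    auc_with_ci,
    calibrate,
    grade_auc,
    light_band,
    normality_gate,
    roc_points,
    se_sp_at_cut,
    spearman_rho,
    youden_cutpoint,
)

# Fixed two-class sample (normals, rounded to 3 dp so ties can occur);
# reference AUC and DeLong 95% CI computed independently with R pROC
# (ci.auc, method="delong") and frozen here.
PROC_NEG = np.array([
    5.609, 2.92, 6.501, 6.881, 1.098, 2.396, 5.256, 4.368, 4.966, 3.294,
    6.759, 6.556, 5.132, 7.254, 5.935, 3.281, 5.738, 3.082, 6.757, 4.9,
    4.63, 3.638, 7.445, 4.691, 4.143, 4.296, 6.065, 5.731, 5.825, 5.862,
    9.283, 4.187, 3.976, 3.372, 6.232, 7.258, 4.772, 3.32, 3.351, 6.301,
])
PROC_POS = np.array([
    9.487, 9.086, 6.669, 8.464, 8.233, 8.437, 9.743, 8.447, 9.358, 8.135,
    8.578, 9.263, 5.086, 7.361, 7.059, 6.722, 7.45, 10.99, 6.268, 9.937,
    4.634, 7.33, 8.326, 9.172, 9.422, 9.587, 7.303, 7.075, 9.716, 7.617,
    5.449, 5.733, 6.161, 8.994, 8.285, 9.381, 7.145, 8.317, 9.251, 7.381,
    8.914, 6.676, 7.274, 7.237, 5.608, 8.974, 7.061, 8.025, 8.961, 8.893,
    9.331, 7.803, 7.153, 7.841, 4.625, 5.106, 5.355, 6.006, 8.8, 6.189,
])
PROC_AUC = 0.8825
PROC_CI = (0.8161506942, 0.9488493058)


def two_class(neg, pos):
    scores = np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(len(neg), bool), np.ones(len(pos), bool)])
    return scores, labels


def brute_force_auc(neg, pos):
    gt = np.sum(pos[:, None] > neg[None, :])
    eq = np.sum(pos[:, None] == neg[None, :])
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman_rho(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_small_permutation(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [2, 1, 3, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNormalityGate:
    def test_uniform_sample_flagged_non_normal(self):
        vals = np.random.default_rng(0).uniform(0, 1, 2000)
        assert not normality_gate(vals).normal

    def test_too_small(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])

    def test_gaussian_sample_usually_passes(self):
        """Size of the test: a true normal sample (n=500) passes at alpha
        0.05 in at least 90% of seeds."""
        passes = sum(
            normality_gate(np.random.default_rng(seed).normal(size=500)).normal
            for seed in range(50)
        )
        assert passes >= 45

    def test_subsampling_large_input(self):
        vals = np.random.default_rng(1).normal(size=8000)
        res = normality_gate(vals)
        assert 0.0 <= res.p_value <= 1.0


class TestRocPoints:
    def test_perfect_separation_reaches_corner(self):
        scores, labels = two_class(np.array([1.0, 2.0]), np.array([10.0, 11.0]))
        pts = roc_points(scores, labels)
        assert any(f == 0.0 and t == 1.0 for f, t, _ in pts)
        assert pts[0][0] == 0.0 and pts[-1][1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1.0, 2.0], [True, True])


class TestAuc:
    def test_perfect_separation(self):
        scores, labels = two_class(np.array([1.0, 2.0]), np.array([10.0, 11.0]))
        auc, ci = auc_with_ci(scores, labels)
        assert auc == 1.0
        assert ci == (1.0, 1.0)

    def test_exhaustive_pair_example(self):
        scores, labels = two_class(np.array([1.0, 2.0, 3.0]), np.array([2.5, 4.0, 5.0]))
        auc, _ = auc_with_ci(scores, labels)
        assert auc == 8 / 9

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            m, n = rng.integers(5, 80, 2)
            pos = np.round(rng.normal(1, 1, m), 1)  # coarse grid forces ties
            neg = np.round(rng.normal(0, 1, n), 1)
            scores, labels = two_class(neg, pos)
            auc, _ = auc_with_ci(scores, labels)
            assert auc == brute_force_auc(neg, pos)

    def test_delong_ci_matches_independent_reference(self):
        scores, labels = two_class(PROC_NEG, PROC_POS)
        auc, ci = auc_with_ci(scores, labels)
        assert auc == pytest.approx(PROC_AUC, abs=1e-10)
        assert ci[0] == pytest.approx(PROC_CI[0], abs=1e-9)
        assert ci[1] == pytest.approx(PROC_CI[1], abs=1e-9)

    def test_null_symmetry(self):
        """Label permutations give AUC ~ 0.5 on average."""
        rng = np.random.default_rng(5)
        scores = rng.normal(size=100)
        aucs = []
        for _ in range(100):
            labels = np.zeros(100, bool)
            labels[rng.permutation(100)[:50]] = True
            aucs.append(auc_with_ci(scores, labels)[0])
        assert abs(np.mean(aucs) - 0.5) < 0.03


class TestYouden:
    def test_tie_broken_by_sensitivity(self):
        scores, labels = two_class(np.array([1.0, 2.0, 3.0]), np.array([2.5, 4.0, 5.0]))
        cut, se, sp = youden_cutpoint(scores, labels, grid=None)
        assert cut == 2.5
        assert se == pytest.approx(100.0)
        assert sp == pytest.approx(200 / 3)

    def test_perfect_separation(self):
        scores, labels = two_class(np.array([1.0, 2.0]), np.array([10.0, 11.0]))
        cut, se, sp = youden_cutpoint(scores, labels)
        assert se == 100.0 and sp == 100.0
        assert 2.0 < cut <= 10.0

    def test_degenerate_scores(self):
        cut, se, sp = youden_cutpoint([3.0, 3.0, 3.0], [False, True, True], grid=None)
        assert cut == 3.0 and se == 100.0 and sp == 0.0

    def test_reported_se_sp_consistent_with_confusion_matrix(self):
        rng = np.random.default_rng(8)
        scores, labels = two_class(rng.normal(0, 1, 60), rng.normal(1.5, 1, 50))
        for direction in (HIGH, LOW):
            cut, se, sp = youden_cutpoint(scores, labels, direction)
            assert (se, sp) == se_sp_at_cut(scores, labels, cut, direction)


@given(seed=st.integers(0, 1000))
@settings(max_examples=30, deadline=None)
def test_direction_symmetry(seed):
    """Negating scores and flipping the direction leaves AUC, cut-point
    (up to sign) and Se/Sp unchanged."""
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(0, 1, 40), 1)
    labels = rng.random(40) < 0.5
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    auc1, _ = auc_with_ci(scores, labels, HIGH)
    auc2, _ = auc_with_ci(-scores, labels, LOW)
    assert auc1 == auc2
    c1, se1, sp1 = youden_cutpoint(scores, labels, HIGH, grid=None)
    c2, se2, sp2 = youden_cutpoint(-scores, labels, LOW, grid=None)
    assert (se1, sp1) == (se2, sp2)
    assert c1 == -c2


class TestGrading:
    @pytest.mark.parametrize(
        "auc, grade",
        [
            (0.948, "excellent"),
            (0.791, "fair"),
            (0.65, "poor"),
            (0.9, "excellent"),
            (0.8, "good"),
            (0.7, "fair"),
            (1.0, "excellent"),
        ],
    )
    def test_grades(self, auc, grade):
        assert grade_auc(auc) == grade

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            grade_auc(1.2)


class TestLightBand:
    @pytest.mark.parametrize(
        "sed, mod, expected",
        [
            ((4.0), 8.9, (4.1, 8.8)),
            (3.5, 39.3, (3.6, 39.2)),
            (4.5, 16.5, (4.6, 16.4)),
        ],
    )
    def test_band_from_cutpoints(self, sed, mod, expected):
        lo, hi = light_band(sed, mod)
        assert lo == pytest.approx(expected[0], abs=1e-9)
        assert hi == pytest.approx(expected[1], abs=1e-9)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            light_band(1.0, 1.1)


class TestCalibrate:
    def make_table(self, rng, n=120, separated=True):
        import pandas as pd

        mu = {"sedentary": 1.0, "light": 10.0, "moderate": 30.0}
        spread = 0.5 if separated else 6.0
        rows = []
        for intensity, m in mu.items():
            counts = np.abs(rng.normal(m, spread, n))
            met = {"sedentary": 1.0, "light": 2.0, "moderate": 4.0}[intensity]
            for c in counts:
                rows.append(
                    {
                        "participant_id": "P01",
                        "location": "waist",
                        "epoch_start": len(rows) * 1.0,
                        "svm_gs": c,
                        "met": met + rng.normal(0, 0.05),
                        "intensity": intensity,
                        "activity_label": intensity,
                        "is_fms": intensity == "light",
                    }
                )
        return pd.DataFrame(rows)

    def test_separated_classes_grade_excellent(self):
        table = self.make_table(np.random.default_rng(2))
        report = calibrate(table)
        cps = report.cutpoints["waist"]
        assert cps.sedentary.grade == "excellent"
        assert cps.moderate.grade == "excellent"
        assert cps.sedentary.cutpoint < cps.moderate.cutpoint
        lo, hi = cps.light_band
        assert cps.sedentary.cutpoint < lo <= hi < cps.moderate.cutpoint

    def test_missing_category_named_in_error(self):
        table = self.make_table(np.random.default_rng(2))
        with pytest.raises(ValueError, match="moderate"):
            calibrate(table[table.intensity != "moderate"])

    def test_study_cutpoints_ordered(self, small_calibration):
        _, report = small_calibration
        for loc, cps in report.cutpoints.items():
            assert cps.sedentary.cutpoint < cps.moderate.cutpoint
            rho, p = report.spearman[loc]
            assert rho > 0.5
            assert not report.normality[loc].normal  # pooled counts are skewed
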