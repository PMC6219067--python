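import numpy as np
import pytest

from fastla import (
    PairedMeasurements,
    agreement_report,
    bland_altman,
    coefficient_of_variation,
    passing_bablok,
    pearson_r,
    roc_analysis,
)
from fastla.errors import DomainError


def pb_oracle(x, y):
    """Exhaustive pairwise-slope enumeration with the canonical tie/offset rules."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            if dx == 0:
                continue
            s = (y[j] - y[i]) / dx
            if s == -1.0:
                continue
            slopes.append(s)
    s = np.sort(slopes)
    k = int(np.sum(s < -1.0))
    m = len(s)
    if m % 2 == 1:
        slope = s[(m - 1) // 2 + k]
    else:
        slope = 0.5 * (s[m // 2 - 1 + k] + s[m // 2 + k])
    return slope, np.median(y - slope * x)


def mw_auc(scores, labels):
    """Mann-Whitney pairwise estimator, ties counted one half."""
    pos = scores[labels]
    neg = scores[~labels]
    gt = np.sum(pos[:, None] > neg[None, :])
    eq = np.sum(pos[:, None] == neg[None, :])
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson_r(PairedMeasurements(x, x)) == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(PairedMeasurements(x, -2 * x + 3)) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert pearson_r(PairedMeasurements(x, y)) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson_r(PairedMeasurements(np.ones(5), np.arange(5.0)))


class TestPassingBablok:
    def test_identity_line(self):
        x = np.arange(1.0, 9.0)
        slope, intercept, *_ = passing_bablok(PairedMeasurements(x, x))
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_affine_line(self):
        x = np.arange(1.0, 9.0)
        slope, intercept, *_ = passing_bablok(PairedMeasurements(x, 2 * x + 1))
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.random(10) * 10
        y = 1.3 * x + r.normal(0, 0.8, 10)
        slope, intercept, *_ = passing_bablok(PairedMeasurements(x, y))
        o_slope, o_intercept = pb_oracle(x, y)
        assert slope == pytest.approx(o_slope, abs=1e-12)
        assert intercept == pytest.approx(o_intercept, abs=1e-12)

    def test_scale_equivariance(self, rng):
        # well-separated x keeps every pairwise slope positive, so the
        # procedure's -1-slope offset is untouched by the rescaling
        x = np.arange(12.0) + rng.random(12) * 0.2
        y = 0.9 * x + rng.normal(0, 0.1, 12)
        a, b = 2.5, -1.0
        s1, i1, *_ = passing_bablok(PairedMeasurements(x, y))
        s2, i2, *_ = passing_bablok(PairedMeasurements(x, a * y + b))
        assert s2 == pytest.approx(a * s1, rel=1e-9)
        assert i2 == pytest.approx(a * i1 + b, rel=1e-9, abs=1e-9)

    def test_all_x_identical_rejected(self):
        with pytest.raises(DomainError):
            passing_bablok(PairedMeasurements(np.ones(5), np.arange(5.0)))


class TestBlandAltman:
    def test_identical_methods(self):
        x = np.arange(5.0)
        assert bland_altman(PairedMeasurements(x, x)) == (0.0, 0.0, 0.0)

    def test_constant_difference(self):
        x = np.array([2.0, 3.0, 4.0])
        bias, lo, hi = bland_altman(PairedMeasurements(x, x - 1.0))
        assert (bias, lo, hi) == (1.0, 1.0, 1.0)

    def test_matches_direct_computation(self, rng):
        x = rng.random(20)
        y = rng.random(20)
        d = x - y
        bias, lo, hi = bland_altman(PairedMeasurements(x, y))
        assert bias == pytest.approx(d.mean(), abs=1e-12)
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)


class TestCoefficientOfVariation:
    def test_identical_pairs_zero(self):
        x = np.array([8.0, 9.0, 10.0])
        assert coefficient_of_variation(PairedMeasurements(x, x)) == 0.0

    def test_hand_computed_fixture(self):
        pairs = PairedMeasurements([10.0, 10.0, 9.0], [10.0, 10.0, 11.0])
        # d² = {0, 0, 4}; grand mean 10 -> sqrt((4/3)/2)/10*100
        assert coefficient_of_variation(pairs) == pytest.approx(8.165, abs=1e-3)

    def test_scale_invariance(self, rng):
        x = 5 + rng.random(10)
        y = 5 + rng.random(10)
        cv1 = coefficient_of_variation(PairedMeasurements(x, y))
        cv2 = coefficient_of_variation(PairedMeasurements(3 * x, 3 * y))
        assert cv1 == pytest.approx(cv2, rel=1e-12)

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(DomainError):
            coefficient_of_variation(PairedMeasurements([-1.0, 0, 1], [1.0, 0, -1]))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis(np.r_[np.full(5, 2.0), np.zeros(5)],
                           np.r_[np.ones(5), np.zeros(5)])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_all_ties_give_half(self):
        res = roc_analysis(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
        assert res.auc == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney(self, seed):
        r = np.random.default_rng(seed)
        scores = np.round(r.normal(0, 1, 30), 1)  # rounding forces ties
        labels = np.r_[np.ones(15), np.zeros(15)].astype(bool)
        scores[labels] += 0.8
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(mw_auc(scores, labels), abs=1e-12)

    def test_operating_point_on_empirical_curve(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        scores[labels] += 1.0
        res = roc_analysis(scores, labels)
        sens = np.mean(scores[labels] >= res.threshold)
        spec = np.mean(scores[~labels] < res.threshold)
        assert res.sensitivity == pytest.approx(sens, abs=1e-12)
        assert res.specificity == pytest.approx(spec, abs=1e-12)

    def test_direction_less(self):
        # marker decreases with disease (like strain): cases score lower
        scores = np.r_[np.full(5, 10.0), np.full(5, 30.0)]
        labels = np.r_[np.ones(5), np.zeros(5)]
        res = roc_analysis(scores, labels, direction="less")
        assert res.auc == 1.0
        assert 10.0 <= res.threshold <= 30.0

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_analysis(np.arange(5.0), np.ones(5))


def test_agreement_report_combines_all(rng):
    x = rng.random(15) * 10 + 20
    y = x + rng.normal(0, 0.4, 15)
    res = agreement_report(PairedMeasurements(x, y, label="eps_s"))
    assert -1 <= res.r <= 1
    assert res.loa_low <= res.bias <= res.loa_high
    assert res.cv_percent >= 0
    assert res.label == "eps_s"
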