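"""ROC construction, AUC statistics, DeLong intervals and Youden optimum."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from cutcalib import (
    DegenerateDataError,
    ValidationError,
    auc_ci,
    binarize,
    mann_whitney_auc,
    optimal_cutpoint,
    roc_curve,
)
from cutcalib.roc import DEFAULT_INTENSITY_MAPS

from conftest import make_samples, random_two_class


def brute_force_auc(values, labels, direction="high_positive"):
    """Independent oracle: explicit loop over all (pos, neg) pairs."""
    values = np.asarray(values, dtype=float)
    pos = values[np.asarray(labels) == 1]
    neg = values[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p == q:
                total += 0.5
            elif (p > q) == (direction == "high_positive"):
                total += 1.0
    return total / (len(pos) * len(neg))


def trapezoid_auc(curve):
    """Independent oracle: trapezoidal integral of the ROC polygon."""
    fpr = 1.0 - curve.specificity
    tpr = curve.sensitivity
    order = np.lexsort((tpr, fpr))  # walk the polygon: fpr, then tpr ascending
    return float(np.trapezoid(tpr[order], fpr[order]))


def exhaustive_youden(values, labels, direction="high_positive"):
    """Independent oracle: classify at every candidate threshold directly.

    Tie policy mirrors the documented rule: observed values beat the
    sentinel endpoint, then higher sensitivity, then the more sensitive
    threshold for the direction.
    """
    values = np.asarray(values, dtype=float)
    pos = values[np.asarray(labels) == 1]
    neg = values[np.asarray(labels) == 0]
    uniq = np.unique(values)
    candidates = [(uniq[0] - 1.0, False)] + [(c, True) for c in uniq]
    rows = []
    for c, observed in candidates:
        if direction == "high_positive":
            sens, spec = np.mean(pos > c), np.mean(neg <= c)
        else:
            sens, spec = np.mean(pos <= c), np.mean(neg > c)
        rows.append((c, observed, sens, spec, sens + spec - 1.0))
    jmax = max(r[4] for r in rows)
    ties = [r for r in rows if r[4] >= jmax - 1e-12]
    if any(r[1] for r in ties):
        ties = [r for r in ties if r[1]]
    smax = max(r[2] for r in ties)
    ties = [r for r in ties if r[2] >= smax - 1e-12]
    pick = min(ties) if direction == "high_positive" else max(ties)
    return pick[0], pick[2], pick[3], pick[4]


class TestBinarize:
    @pytest.mark.parametrize(
        "code, class_name, expected",
        [(4, "moderate", 1), (5, "moderate", 1), (3, "moderate", 0),
         (1, "sedentary", 1), (2, "sedentary", 1), (3, "sedentary", 0),
         (5, "vigorous", 1), (4, "vigorous", 0)],
    )
    def test_code_to_criterion(self, code, class_name, expected):
        samples = make_samples([(1000, code)])
        _, labels = binarize(samples, DEFAULT_INTENSITY_MAPS[class_name])
        assert labels[0] == expected

    def test_cpm_carried_through(self):
        samples = make_samples([(123.0, 4), (456.0, 1)])
        cpm, _ = binarize(samples, DEFAULT_INTENSITY_MAPS["moderate"])
        np.testing.assert_allclose(cpm, [123.0, 456.0])


class TestAuc:
    def test_pair_count_example(self):
        values = [5, 7, 9, 1, 2, 6]
        labels = [1, 1, 1, 0, 0, 0]
        assert mann_whitney_auc(values, labels) == pytest.approx(8 / 9)
        assert brute_force_auc(values, labels) == pytest.approx(8 / 9)

    def test_perfect_separation(self):
        curve = roc_curve([10, 11, 1, 2], [1, 1, 0, 0])
        assert curve.auc == 1.0
        assert curve.optimal_sens == 1.0 and curve.optimal_spec == 1.0

    def test_sens_spec_at_threshold(self):
        curve = roc_curve([4, 6, 8, 1, 2, 5], [1, 1, 1, 0, 0, 0])
        i = int(np.nonzero(curve.thresholds == 5.0)[0][0])
        assert curve.sensitivity[i] == pytest.approx(2 / 3)
        assert curve.specificity[i] == pytest.approx(1.0)

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateDataError, match="degenerate ROC"):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_matches_brute_force_and_sklearn_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            values, labels = random_two_class(rng)
            auc = mann_whitney_auc(values, labels)
            assert auc == pytest.approx(brute_force_auc(values, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    def test_trapezoid_equals_pair_count(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            values, labels = random_two_class(rng)
            curve = roc_curve(values, labels)
            assert trapezoid_auc(curve) == pytest.approx(curve.auc, abs=1e-9)

    def test_direction_flip_complements_auc(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            values, labels = random_two_class(rng)
            high = mann_whitney_auc(values, labels, "high_positive")
            low = mann_whitney_auc(values, labels, "low_positive")
            assert high + low == pytest.approx(1.0, abs=1e-12)


class TestMonotonicity:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_sens_nonincreasing_spec_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        values, labels = random_two_class(rng)
        curve = roc_curve(values, labels, "high_positive")
        assert np.all(np.diff(curve.sensitivity) <= 1e-12)
        assert np.all(np.diff(curve.specificity) >= -1e-12)


class TestOptimalCutpoint:
    def test_tie_breaks_toward_sensitivity(self):
        # J = 2/3 at both c=2 (sens 1) and c=5 (sens 2/3): pick c=2
        curve = roc_curve([4, 6, 8, 1, 2, 5], [1, 1, 1, 0, 0, 0])
        threshold, sens, spec, j = optimal_cutpoint(curve)
        assert threshold == 2.0
        assert sens == pytest.approx(1.0)
        assert j == pytest.approx(2 / 3)

    def test_perfect_separation_has_unit_youden(self):
        curve = roc_curve([10, 11, 1, 2], [1, 1, 0, 0])
        assert curve.youden_j == pytest.approx(1.0)

    def test_low_positive_direction_reports_data_value(self):
        curve = roc_curve([1, 2, 10, 11], [1, 1, 0, 0], "low_positive")
        assert curve.optimal_threshold == 2.0
        assert curve.youden_j == pytest.approx(1.0)

    def test_equals_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            values, labels = random_two_class(rng)
            direction = "high_positive" if rng.random() < 0.5 else "low_positive"
            curve = roc_curve(values, labels, direction)
            got = optimal_cutpoint(curve)
            want = exhaustive_youden(values, labels, direction)
            assert got[3] == pytest.approx(want[3], abs=1e-12)
            assert got[0] == want[0]


class TestAucCi:
    def test_perfect_separation_gives_point_interval(self):
        curve = roc_curve([10, 11, 1, 2], [1, 1, 0, 0])
        with pytest.warns(UserWarning, match="zero DeLong variance"):
            lo, hi = auc_ci(curve, [10, 11, 1, 2], [1, 1, 0, 0])
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_contains_auc_and_is_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            values, labels = random_two_class(rng)
            curve = roc_curve(values, labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lo, hi = auc_ci(curve, values, labels)
            assert 0.0 <= lo <= curve.auc <= hi <= 1.0

    def test_close_to_bootstrap_percentile_interval(self):
        """DeLong vs. a 10,000-resample stratified bootstrap on a tiny sample."""
        values = np.array([5, 7, 9, 1, 2, 6], dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0])
        curve = roc_curve(values, labels)
        lo, hi = auc_ci(curve, values, labels)
        assert lo <= 8 / 9 <= hi
        rng = np.random.default_rng(123)
        pos, neg = values[labels == 1], values[labels == 0]
        boots = []
        for _ in range(10_000):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            boots.append(
                mann_whitney_auc(
                    np.concatenate([bp, bn]),
                    np.concatenate([np.ones(len(bp), int), np.zeros(len(bn), int)]),
                )
            )
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        assert lo == pytest.approx(blo, abs=0.05)
        assert hi == pytest.approx(bhi, abs=0.05)

    def test_invalid_level_rejected(self):
        curve = roc_curve([4, 6, 1, 2], [1, 1, 0, 0])
        with pytest.raises(ValidationError, match="level"):
            auc_ci(curve, [4, 6, 1, 2], [1, 1, 0, 0], level=1.5)
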