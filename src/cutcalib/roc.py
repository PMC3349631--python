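"""Empirical ROC analysis for count-threshold calibration.

Each intensity class is calibrated by turning the DO codes into a binary
criterion (e.g. moderate: codes 4–5 positive), sweeping a threshold over
the observed counts·min⁻¹ values, and picking the threshold that maximizes
the Youden index J = sensitivity + specificity − 1 — the operational
reading of "sensitivity and specificity both maximized".

Directionality matters: sedentary behaviour is flagged by LOW counts, so
its published rule is "positive when cpm ≤ c" (``low_positive``), whereas
moderate and vigorous use "positive when cpm > c" (``high_positive``).

The AUC is computed as the Mann–Whitney pair statistic
(concordant pairs + ½·tied pairs) / (n₁·n₀) — the probability that a
random criterion-positive interval has more counts (``high_positive``) or
fewer counts (``low_positive``) than a random criterion-negative one. Its
confidence interval uses DeLong's structural-components variance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .datatypes import AlignedSample
from .exceptions import DegenerateDataError, ValidationError

Direction = Literal["low_positive", "high_positive"]

SEDENTARY = "sedentary"
MODERATE = "moderate"
VIGOROUS = "vigorous"
INTENSITY_CLASSES = (SEDENTARY, MODERATE, VIGOROUS)


@dataclass(frozen=True)
class IntensityMap:
    """How one intensity class maps onto SOFIT codes and a threshold rule.

    ``positive_codes`` defines the DO criterion; ``direction`` the side of
    the cut-point that is classified positive (``low_positive``: cpm ≤ c;
    ``high_positive``: cpm > c).
    """

    class_name: str
    positive_codes: frozenset[int]
    direction: Direction

    def __post_init__(self) -> None:
        if not self.positive_codes or not self.positive_codes <= {1, 2, 3, 4, 5}:
            raise ValidationError(
                f"positive_codes must be a non-empty subset of 1-5, "
                f"got {set(self.positive_codes)}"
            )
        if self.direction not in ("low_positive", "high_positive"):
            raise ValidationError(f"unknown direction {self.direction!r}")


#: SOFIT code → intensity criterion used throughout: codes 1-2 (lying,
#: sitting) are sedentary, code 3 (standing) light, 4 walking = moderate,
#: 5 very active = vigorous. Moderate is cumulative (codes 4 AND 5 positive).
DEFAULT_INTENSITY_MAPS: dict[str, IntensityMap] = {
    SEDENTARY: IntensityMap(SEDENTARY, frozenset({1, 2}), "low_positive"),
    MODERATE: IntensityMap(MODERATE, frozenset({4, 5}), "high_positive"),
    VIGOROUS: IntensityMap(VIGOROUS, frozenset({5}), "high_positive"),
}


@dataclass
class RocCurve:
    """Full sensitivity/specificity profile over candidate thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: Direction
    auc_ci: tuple[float, float] | None = None
    optimal_threshold: float = float("nan")
    optimal_sens: float = float("nan")
    optimal_spec: float = float("nan")
    youden_j: float = float("nan")

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.specificity = np.asarray(self.specificity, dtype=float)
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC {self.auc} outside [0, 1]")
        for arr, name in ((self.sensitivity, "sensitivity"), (self.specificity, "specificity")):
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"{name} outside [0, 1]")


def binarize(
    samples: Iterable[AlignedSample], imap: IntensityMap
) -> tuple[np.ndarray, np.ndarray]:
    """Turn aligned samples into (cpm, 0/1 criterion label) arrays."""
    rows = list(samples)
    cpm = np.array([s.cpm for s in rows], dtype=float)
    positive = np.fromiter(
        (s.code in imap.positive_codes for s in rows), dtype=bool, count=len(rows)
    )
    return cpm, positive.astype(np.int64)


def _split(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValidationError("values and labels must be 1-d arrays of equal length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValidationError("labels must be 0/1")
    pos, neg = values[labels == 1], values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError(
            "degenerate ROC: need at least one positive and one negative label"
        )
    return pos, neg


def mann_whitney_auc(values, labels, direction: Direction = "high_positive") -> float:
    """Pair-counting AUC: (concordant + ½·ties) / (n₁·n₀), via midranks."""
    pos, neg = _split(values, labels)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    # rank-sum identity for P(pos > neg) + ½ P(pos = neg)
    auc_high = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0) / (
        len(pos) * len(neg)
    )
    return float(auc_high) if direction == "high_positive" else float(1.0 - auc_high)


def roc_curve(values, labels, direction: Direction = "high_positive") -> RocCurve:
    """Sweep candidate thresholds and build the empirical ROC profile.

    Candidate thresholds are the unique observed values plus one sentinel
    below the minimum, so both trivial operating points (everything
    positive / everything negative) appear on the curve. The optimal point
    (max Youden J) is filled in; the confidence interval is left for
    :func:`auc_ci`.
    """
    pos, neg = _split(values, labels)
    uniq = np.unique(np.concatenate([pos, neg]))
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # P(v > c) per class via binary search on the sorted values
    n_pos_gt = len(pos) - np.searchsorted(pos_sorted, thresholds, side="right")
    n_neg_gt = len(neg) - np.searchsorted(neg_sorted, thresholds, side="right")
    if direction == "high_positive":
        sens = n_pos_gt / len(pos)
        spec = 1.0 - n_neg_gt / len(neg)
    else:
        sens = 1.0 - n_pos_gt / len(pos)
        spec = n_neg_gt / len(neg)
    curve = RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=mann_whitney_auc(values, labels, direction),
        direction=direction,
    )
    (curve.optimal_threshold, curve.optimal_sens,
     curve.optimal_spec, curve.youden_j) = optimal_cutpoint(curve)
    return curve


def optimal_cutpoint(curve: RocCurve) -> tuple[float, float, float, float]:
    """Threshold maximizing Youden J = sens + spec − 1.

    Ties in J are broken toward the threshold with the higher sensitivity —
    the calibration should not miss activity — which for ``high_positive``
    means the lower threshold. Among exact ties, observed data values are
    preferred over the sentinel endpoint so the reported cut-point is a
    value that actually occurred.
    """
    if len(curve.thresholds) == 0:
        raise ValidationError("empty ROC curve")
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.nonzero(j >= j.max() - 1e-12)[0]
    if len(best) > 1 and 0 in best:  # sentinel ties an observed value: drop it
        observed = best[best != 0]
        best = observed if len(observed) else best
    sens_at_best = curve.sensitivity[best]
    best = best[sens_at_best >= sens_at_best.max() - 1e-12]
    thr_at_best = curve.thresholds[best]
    idx = best[np.argmin(thr_at_best)] if curve.direction == "high_positive" \
        else best[np.argmax(thr_at_best)]
    return (
        float(curve.thresholds[idx]),
        float(curve.sensitivity[idx]),
        float(curve.specificity[idx]),
        float(j[idx]),
    )


def _delong_variance(values, labels, direction: Direction) -> float:
    pos, neg = _split(values, labels)
    if direction == "low_positive":
        pos, neg = -pos, -neg
    # structural components: per-positive and per-negative placement values
    n1, n0 = len(pos), len(neg)
    neg_sorted = np.sort(neg)
    v10 = (
        np.searchsorted(neg_sorted, pos, side="left")
        + 0.5 * (np.searchsorted(neg_sorted, pos, side="right")
                 - np.searchsorted(neg_sorted, pos, side="left"))
    ) / n0
    pos_sorted = np.sort(pos)
    v01 = (
        (n1 - np.searchsorted(pos_sorted, neg, side="right"))
        + 0.5 * (np.searchsorted(pos_sorted, neg, side="right")
                 - np.searchsorted(pos_sorted, neg, side="left"))
    ) / n1
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


def auc_ci(
    curve: RocCurve, values, labels, level: float = 0.95
) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, clipped to [0, 1].

    A zero-variance (perfectly separated) sample yields a degenerate point
    interval, reported with a warning rather than an error.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    var = _delong_variance(values, labels, curve.direction)
    if var <= 0.0:
        warnings.warn(
            "zero DeLong variance (perfect separation); returning a point interval",
            stacklevel=2,
        )
        ci = (curve.auc, curve.auc)
    else:
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        ci = (max(0.0, curve.auc - half), min(1.0, curve.auc + half))
    curve.auc_ci = ci
    return ci
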