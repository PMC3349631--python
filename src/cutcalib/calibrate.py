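"""Cut-point derivation: the scikit-learn-style calibration estimator.

:class:`CutPointCalibrator` is fit on calibration-activity data — one
counts·min⁻¹ value and one SOFIT code per 10-s interval — and learns three
ROC-optimal thresholds:

* sedentary:  positive when cpm ≤ c (codes 1–2 are the criterion)
* moderate:   positive when cpm > c (codes 4–5)
* vigorous:   positive when cpm > c (code 5)

Light activity is the residual band sedentary < cpm ≤ moderate, so the
thresholds must be strictly ordered; a violation raises instead of being
silently reordered, because it indicates the input data cannot support
the three-class calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import CALIBRATION, AlignedSample
from .exceptions import DegenerateDataError, OrderingError, ValidationError
from .roc import (
    DEFAULT_INTENSITY_MAPS,
    INTENSITY_CLASSES,
    MODERATE,
    SEDENTARY,
    VIGOROUS,
    IntensityMap,
    RocCurve,
    auc_ci,
    roc_curve,
)

INTENSITY_LABELS = ("sedentary", "light", "moderate", "vigorous")


@dataclass
class CutPointSet:
    """Three derived thresholds in counts·min⁻¹ with their ROC provenance.

    Classification rules: sedentary iff cpm ≤ sedentary_cpm; vigorous iff
    cpm > vigorous_cpm; moderate iff moderate_cpm < cpm ≤ vigorous_cpm;
    light is the residual band.
    """

    sedentary_cpm: float
    moderate_cpm: float
    vigorous_cpm: float
    curves: dict[str, RocCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sedentary_cpm < self.moderate_cpm < self.vigorous_cpm:
            raise OrderingError(
                f"cut-points must satisfy sedentary < moderate < vigorous, got "
                f"{self.sedentary_cpm:g} / {self.moderate_cpm:g} / "
                f"{self.vigorous_cpm:g}; inspect the calibration data — the "
                "code-conditional count distributions may be inverted or "
                "too overlapped"
            )

    def threshold(self, class_name: str) -> float:
        return {
            SEDENTARY: self.sedentary_cpm,
            MODERATE: self.moderate_cpm,
            VIGOROUS: self.vigorous_cpm,
        }[class_name]

    def classify(self, cpm) -> np.ndarray:
        """Band classification of cpm values into the four intensity labels."""
        cpm = np.asarray(cpm, dtype=float)
        out = np.full(cpm.shape, "light", dtype=object)
        out[cpm <= self.sedentary_cpm] = "sedentary"
        out[cpm > self.moderate_cpm] = "moderate"
        out[cpm > self.vigorous_cpm] = "vigorous"
        return out.astype(str)

    def to_dict(self) -> dict:
        payload = {}
        for name in INTENSITY_CLASSES:
            entry: dict = {
                "threshold_cpm": self.threshold(name),
                "rule": "<=" if name == SEDENTARY else ">",
            }
            curve = self.curves.get(name)
            if curve is not None:
                entry.update(
                    sensitivity=curve.optimal_sens,
                    specificity=curve.optimal_spec,
                    youden_j=curve.youden_j,
                    auc=curve.auc,
                    auc_ci=list(curve.auc_ci) if curve.auc_ci else None,
                )
            payload[name] = entry
        return payload

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CutPointSet":
        data = json.loads(Path(path).read_text())
        try:
            return cls(
                sedentary_cpm=float(data[SEDENTARY]["threshold_cpm"]),
                moderate_cpm=float(data[MODERATE]["threshold_cpm"]),
                vigorous_cpm=float(data[VIGOROUS]["threshold_cpm"]),
            )
        except KeyError as exc:
            raise ValidationError(f"cut-point JSON missing entry: {exc}") from exc


class CutPointCalibrator(BaseEstimator):
    """Derive ROC-optimal intensity cut-points from criterion-coded counts.

    Parameters
    ----------
    intensity_maps : mapping of class name to IntensityMap, optional
        Criterion definition per class; defaults to the SOFIT mapping
        (sedentary {1,2} ≤, moderate {4,5} >, vigorous {5} >).
    ci_level : float, default 0.95
        Confidence level for the DeLong AUC interval.

    Attributes
    ----------
    cutpoints_ : CutPointSet
        The three ordered thresholds with ROC provenance.
    roc_curves_ : dict of str to RocCurve
        Per-class ROC profile (thresholds, sensitivity, specificity, AUC).
    sedentary_cpm_, moderate_cpm_, vigorous_cpm_ : float
    n_samples_ : int

    Examples
    --------
    >>> cal = CutPointCalibrator().fit(cpm_values, sofit_codes)  # doctest: +SKIP
    >>> cal.cutpoints_.classify([100, 1500, 3000, 6000])         # doctest: +SKIP
    array(['sedentary', 'light', 'moderate', 'vigorous'], ...)
    """

    def __init__(
        self,
        intensity_maps: Mapping[str, IntensityMap] | None = None,
        ci_level: float = 0.95,
    ) -> None:
        self.intensity_maps = intensity_maps
        self.ci_level = ci_level

    def _maps(self) -> Mapping[str, IntensityMap]:
        maps = self.intensity_maps or DEFAULT_INTENSITY_MAPS
        missing = set(INTENSITY_CLASSES) - set(maps)
        if missing:
            raise ValidationError(f"intensity_maps missing classes: {sorted(missing)}")
        return maps

    def fit(self, X, y) -> "CutPointCalibrator":
        """Fit on counts·min⁻¹ values ``X`` and SOFIT codes ``y``.

        ``X`` may be shape (n,) or (n, 1). Every class must see both
        criterion labels, otherwise the ROC is degenerate and an error is
        raised rather than an arbitrary threshold returned.
        """
        cpm = np.asarray(X, dtype=float)
        if cpm.ndim == 2 and cpm.shape[1] == 1:
            cpm = cpm[:, 0]
        if cpm.ndim != 1:
            raise ValidationError(f"X must be (n,) or (n, 1), got shape {cpm.shape}")
        codes = np.asarray(y)
        if codes.shape != cpm.shape:
            raise ValidationError("X and y must have equal length")
        if np.any(cpm < 0) or not np.all(np.isfinite(cpm)):
            raise ValidationError("cpm values must be finite and non-negative")
        if not np.all(np.isin(codes, (1, 2, 3, 4, 5))):
            raise ValidationError("codes must be SOFIT codes 1-5")

        curves: dict[str, RocCurve] = {}
        for name in INTENSITY_CLASSES:
            imap = self._maps()[name]
            labels = np.isin(codes, list(imap.positive_codes)).astype(np.int64)
            try:
                curve = roc_curve(cpm, labels, imap.direction)
            except DegenerateDataError as exc:
                raise DegenerateDataError(f"{name}: {exc}") from exc
            auc_ci(curve, cpm, labels, level=self.ci_level)
            curves[name] = curve

        self.roc_curves_ = curves
        self.cutpoints_ = CutPointSet(
            sedentary_cpm=curves[SEDENTARY].optimal_threshold,
            moderate_cpm=curves[MODERATE].optimal_threshold,
            vigorous_cpm=curves[VIGOROUS].optimal_threshold,
            curves=curves,
        )
        self.sedentary_cpm_ = self.cutpoints_.sedentary_cpm
        self.moderate_cpm_ = self.cutpoints_.moderate_cpm
        self.vigorous_cpm_ = self.cutpoints_.vigorous_cpm
        self.n_samples_ = len(cpm)
        return self

    def predict(self, X) -> np.ndarray:
        """Classify cpm values into sedentary/light/moderate/vigorous bands."""
        if not hasattr(self, "cutpoints_"):
            raise ValidationError("CutPointCalibrator is not fitted yet")
        cpm = np.asarray(X, dtype=float)
        if cpm.ndim == 2 and cpm.shape[1] == 1:
            cpm = cpm[:, 0]
        return self.cutpoints_.classify(cpm)


def derive_cutpoints(
    samples: Iterable[AlignedSample],
    intensity_maps: Mapping[str, IntensityMap] | None = None,
    ci_level: float = 0.95,
    restrict_role: bool = True,
) -> CutPointSet:
    """Derive a :class:`CutPointSet` from aligned samples.

    Pools all participants' calibration-role intervals (no per-participant
    weighting) and fits a :class:`CutPointCalibrator`.
    """
    rows = list(samples)
    if restrict_role:
        rows = [s for s in rows if s.role == CALIBRATION]
    if not rows:
        raise ValidationError("no calibration-role samples")
    cpm = np.array([s.cpm for s in rows], dtype=float)
    codes = np.array([s.code for s in rows], dtype=np.int64)
    cal = CutPointCalibrator(intensity_maps=intensity_maps, ci_level=ci_level)
    cal.fit(cpm, codes)
    return cal.cutpoints_
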