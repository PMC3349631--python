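"""Cross-validation of cut-points on held-out activities.

The derived thresholds are evaluated on activities never used in fitting
(DVD viewing and free-choice play) by building a 2×2 contingency table per
intensity class — rows: DO criterion positive/negative, columns: device
classification positive/negative — and computing sensitivity, specificity,
Cohen's kappa and percent agreement. A perturbation sweep (±90 and ±200
counts·min⁻¹ around the moderate cut-point) quantifies how robust the
agreement statistics are to plausible cut-point error.

Classification is cumulative by default (moderate-positive means
cpm > moderate cut-point regardless of the vigorous threshold), matching
the binary active/inactive framing of the calibration; exclusive band
classification is available via ``band=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibrate import CutPointSet
from .datatypes import CROSS_VALIDATION, AlignedSample
from .exceptions import ValidationError
from .roc import (
    DEFAULT_INTENSITY_MAPS,
    INTENSITY_CLASSES,
    MODERATE,
    IntensityMap,
)

#: moderate cut-point offsets evaluated in the perturbation sweep, in cpm.
#: ±90 is the scale of cut-point disagreement shown to shift MVPA estimates
#: significantly; ±200 the scale argued to matter bio-behaviourally.
DEFAULT_PERTURBATION_DELTAS = (90.0, -90.0, 200.0, -200.0)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Agreement counts; rows = DO criterion, columns = device classification."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValidationError("empty contingency table")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class PerturbationSpec:
    """Offsets (cpm) applied to a cut-point before re-evaluation."""

    deltas: Sequence[float] = DEFAULT_PERTURBATION_DELTAS

    def __post_init__(self) -> None:
        if any(d == 0 for d in self.deltas):
            raise ValidationError("perturbation deltas must be nonzero")


@dataclass
class CrossValResult:
    """Agreement statistics for one intensity class at one threshold.

    Ratios with a zero denominator are ``None`` (with a warning), never
    silently 0 or 1.
    """

    class_name: str
    threshold_cpm: float
    table: ContingencyTable2x2
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    kappa: float | None = field(init=False)
    agreement: float = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        self.sensitivity = t.tp / (t.tp + t.fn) if (t.tp + t.fn) else None
        self.specificity = t.tn / (t.tn + t.fp) if (t.tn + t.fp) else None
        if self.sensitivity is None:
            warnings.warn(
                f"{self.class_name}: no DO-positive samples; sensitivity undefined",
                stacklevel=2,
            )
        if self.specificity is None:
            warnings.warn(
                f"{self.class_name}: no DO-negative samples; specificity undefined",
                stacklevel=2,
            )
        self.agreement = 100.0 * (t.tp + t.tn) / t.n
        self.kappa = kappa(t)


def kappa(table: ContingencyTable2x2) -> float | None:
    """Cohen's kappa: chance-corrected agreement, κ = (p_o − p_e)/(1 − p_e).

    ``p_e`` comes from the row/column margins. When the margins make
    agreement certain by chance (``p_e = 1``), κ is 1 for perfect observed
    agreement and undefined (``None``, with a warning) otherwise.
    """
    n = table.n
    p_o = (table.tp + table.tn) / n
    row_pos, row_neg = table.tp + table.fn, table.fp + table.tn
    col_pos, col_neg = table.tp + table.fp, table.fn + table.tn
    p_e = (row_pos * col_pos + row_neg * col_neg) / (n * n)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        warnings.warn("kappa undefined: chance agreement is 1", stacklevel=2)
        return None
    return (p_o - p_e) / (1.0 - p_e)


def _classify(cpm: np.ndarray, imap: IntensityMap, threshold_cpm: float) -> np.ndarray:
    if imap.direction == "high_positive":
        return cpm > threshold_cpm
    return cpm <= threshold_cpm


def contingency(
    samples: Iterable[AlignedSample],
    imap: IntensityMap,
    threshold_cpm: float,
) -> ContingencyTable2x2:
    """Tabulate DO criterion vs. device classification at one threshold."""
    rows = list(samples)
    if not rows:
        raise ValidationError("no samples to tabulate")
    cpm = np.array([s.cpm for s in rows], dtype=float)
    truth = np.fromiter(
        (s.code in imap.positive_codes for s in rows), dtype=bool, count=len(rows)
    )
    pred = _classify(cpm, imap, threshold_cpm)
    return ContingencyTable2x2(
        tp=int(np.sum(truth & pred)),
        fn=int(np.sum(truth & ~pred)),
        fp=int(np.sum(~truth & pred)),
        tn=int(np.sum(~truth & ~pred)),
    )


def evaluate(
    samples: Iterable[AlignedSample],
    cutpoints: CutPointSet,
    intensity_maps: Mapping[str, IntensityMap] | None = None,
    restrict_role: bool = True,
    band: bool = False,
) -> list[CrossValResult]:
    """One :class:`CrossValResult` per intensity class on held-out samples.

    With ``band=True`` the device classification for the moderate class is
    the exclusive band (moderate < cpm ≤ vigorous) instead of cumulative.
    """
    maps = intensity_maps or DEFAULT_INTENSITY_MAPS
    rows = list(samples)
    if restrict_role:
        rows = [s for s in rows if s.role == CROSS_VALIDATION]
    if not rows:
        raise ValidationError("no cross-validation-role samples")
    results = []
    for name in INTENSITY_CLASSES:
        imap = maps[name]
        threshold = cutpoints.threshold(name)
        if band and name == MODERATE:
            cpm = np.array([s.cpm for s in rows], dtype=float)
            truth = np.fromiter(
                (s.code in imap.positive_codes for s in rows), dtype=bool,
                count=len(rows),
            )
            pred = (cpm > threshold) & (cpm <= cutpoints.vigorous_cpm)
            table = ContingencyTable2x2(
                tp=int(np.sum(truth & pred)),
                fn=int(np.sum(truth & ~pred)),
                fp=int(np.sum(~truth & pred)),
                tn=int(np.sum(~truth & ~pred)),
            )
        else:
            table = contingency(rows, imap, threshold)
        results.append(CrossValResult(name, threshold, table))
    return results


def perturb(
    cutpoint_cpm: float,
    samples: Iterable[AlignedSample],
    imap: IntensityMap,
    spec: PerturbationSpec | None = None,
    restrict_role: bool = True,
) -> list[tuple[float, CrossValResult]]:
    """Re-evaluate one class at each perturbed threshold.

    Returns (perturbed threshold, result) pairs in the order of
    ``spec.deltas``. A perturbed threshold ≤ 0 is rejected: negative count
    thresholds are physically meaningless.
    """
    spec = spec or PerturbationSpec()
    rows = list(samples)
    if restrict_role:
        rows = [s for s in rows if s.role == CROSS_VALIDATION]
    out = []
    for delta in spec.deltas:
        threshold = cutpoint_cpm + delta
        if threshold <= 0:
            raise ValidationError(
                f"perturbed threshold {threshold:g} cpm is not positive "
                f"(delta {delta:+g} on {cutpoint_cpm:g})"
            )
        table = contingency(rows, imap, threshold)
        out.append((threshold, CrossValResult(imap.class_name, threshold, table)))
    return out
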