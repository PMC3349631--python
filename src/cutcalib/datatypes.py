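"""Domain types for paired accelerometer count and direct-observation streams.

The calibration protocol pairs two time series recorded on a shared clock:

* an accelerometer count series on a fixed epoch grid (5-s epochs on the
  device, reintegrated to 10 s for analysis), and
* a direct-observation (DO) series of momentary-time-sampled SOFIT activity
  codes, one code per 10-s interval: 1–3 body position (lying, sitting,
  standing), 4 walking, 5 very active.

Timestamps are held internally as seconds on an arbitrary shared clock
(epoch seconds when parsed from ISO-8601 files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: role of an activity in the protocol: used to fit vs. to evaluate cut-points
CALIBRATION = "calibration"
CROSS_VALIDATION = "cross_validation"
ROLES = (CALIBRATION, CROSS_VALIDATION)

#: valid SOFIT physical-activity codes
SOFIT_CODES = (1, 2, 3, 4, 5)


def _as_time_array(values: Iterable) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("timestamps must be one-dimensional")
    return arr


@dataclass
class EpochSeries:
    """Raw accelerometer counts on a fixed-length epoch grid.

    Parameters
    ----------
    participant_id, session_id : str
        Opaque identifiers; sessions sharing a clock may be aligned.
    epoch_length : int
        Epoch duration in seconds (positive).
    start_times : array of float
        Epoch start times in seconds, strictly increasing with constant
        spacing equal to ``epoch_length``.
    counts : array of int
        Non-negative device counts accumulated per epoch.
    """

    participant_id: str
    session_id: str
    epoch_length: int
    start_times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if int(self.epoch_length) != self.epoch_length or self.epoch_length <= 0:
            raise ValidationError(
                f"epoch_length must be a positive integer, got {self.epoch_length!r}"
            )
        self.epoch_length = int(self.epoch_length)
        self.start_times = _as_time_array(self.start_times)
        counts = np.asarray(self.counts)
        if len(self.start_times) == 0:
            raise ValidationError("no epochs")
        if counts.shape != self.start_times.shape:
            raise ValidationError(
                f"counts length {counts.shape} does not match "
                f"start_times length {self.start_times.shape}"
            )
        if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
            raise ValidationError("counts must be finite integers")
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            first = int(np.argmax(counts < 0))
            raise ValidationError(
                f"negative count {counts[first]} at epoch index {first}"
            )
        self.counts = counts
        _check_regular_grid(self.start_times, self.epoch_length, what="epoch")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass
class ObservationSeries:
    """Momentary-time-sampled direct-observation codes on a fixed interval grid.

    ``codes`` holds one SOFIT code per interval; ``activities`` the protocol
    activity performed during that interval and ``roles`` whether the
    activity belongs to the calibration or the cross-validation set.
    """

    participant_id: str
    session_id: str
    interval_length: int
    interval_starts: np.ndarray
    codes: np.ndarray
    activities: Sequence[str]
    roles: Sequence[str]

    def __post_init__(self) -> None:
        if int(self.interval_length) != self.interval_length or self.interval_length <= 0:
            raise ValidationError(
                f"interval_length must be a positive integer, got {self.interval_length!r}"
            )
        self.interval_length = int(self.interval_length)
        self.interval_starts = _as_time_array(self.interval_starts)
        if len(self.interval_starts) == 0:
            raise ValidationError("no observation intervals")
        codes = np.asarray(self.codes)
        if codes.shape != self.interval_starts.shape:
            raise ValidationError("codes length does not match interval_starts length")
        if not np.all(np.isin(codes, SOFIT_CODES)):
            bad = int(np.argmax(~np.isin(codes, SOFIT_CODES)))
            raise ValidationError(
                f"SOFIT code out of range 1-5 at interval index {bad}: {codes[bad]!r}"
            )
        self.codes = codes.astype(np.int64)
        self.activities = list(self.activities)
        self.roles = list(self.roles)
        if len(self.activities) != len(self.codes) or len(self.roles) != len(self.codes):
            raise ValidationError("activities/roles length does not match codes length")
        for role in self.roles:
            if role not in ROLES:
                raise ValidationError(f"unknown role {role!r}; expected one of {ROLES}")
        _check_regular_grid(self.interval_starts, self.interval_length, what="interval")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class AlignedSample:
    """One 10-s interval joining a count value with its DO code.

    ``cpm`` is the count rescaled to counts·min⁻¹, the unit in which
    cut-points are published: ``cpm = count * (60 / interval_length)``.
    """

    participant_id: str
    activity: str
    role: str
    interval_start: float
    count_10s: float
    cpm: float
    code: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.code not in SOFIT_CODES:
            raise ValidationError(f"SOFIT code out of range: {self.code!r}")
        if self.count_10s < 0 or self.cpm < 0:
            raise ValidationError("counts must be non-negative")


def _check_regular_grid(times: np.ndarray, step: float, what: str) -> None:
    if len(times) < 2:
        return
    diffs = np.diff(times)
    bad = np.nonzero(~np.isclose(diffs, step, rtol=0, atol=1e-6))[0]
    if len(bad):
        i = int(bad[0])
        raise ValidationError(
            f"irregular {what} spacing: {what} at t={times[i + 1]:g} follows "
            f"t={times[i]:g} (spacing {diffs[i]:g}s, expected {step:g}s)"
        )


def aligned_to_frame(samples: Iterable[AlignedSample]) -> pd.DataFrame:
    """Tabulate aligned samples as a DataFrame (one row per 10-s interval)."""
    rows = list(samples)
    return pd.DataFrame(
        {
            "participant": [s.participant_id for s in rows],
            "activity": [s.activity for s in rows],
            "role": [s.role for s in rows],
            "interval_start": [s.interval_start for s in rows],
            "count_10s": [s.count_10s for s in rows],
            "cpm": [s.cpm for s in rows],
            "code": [s.code for s in rows],
        }
    )


def frame_to_aligned(frame: pd.DataFrame) -> list[AlignedSample]:
    """Inverse of :func:`aligned_to_frame`."""
    return [
        AlignedSample(
            participant_id=str(r.participant),
            activity=str(r.activity),
            role=str(r.role),
            interval_start=float(r.interval_start),
            count_10s=float(r.count_10s),
            cpm=float(r.cpm),
            code=int(r.code),
        )
        for r in frame.itertuples(index=False)
    ]
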