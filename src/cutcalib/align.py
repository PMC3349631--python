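"""Epoch reintegration and joining of count and observation streams.

Devices record 5-s epochs to capture the short, sporadic bursts typical of
children's activity; the observation protocol codes 10-s intervals. The
5-s counts are therefore reintegrated (summed) to the 10-s observation
grid and joined interval-by-interval with the DO codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import AlignedSample, EpochSeries, ObservationSeries
from .exceptions import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

#: devices and the observer's watch are synchronized before each session, so
#: a start-time mismatch beyond 1 s signals a data fault, not clock drift.
DEFAULT_TOLERANCE_S = 1.0


@dataclass
class AlignmentReport:
    """Bookkeeping for one alignment pass."""

    n_matched: int = 0
    n_unmatched_obs: int = 0
    n_unmatched_epochs: int = 0
    dropped_trailing_epochs: int = 0

    def __post_init__(self) -> None:
        for name in ("n_matched", "n_unmatched_obs", "n_unmatched_epochs",
                     "dropped_trailing_epochs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def __add__(self, other: "AlignmentReport") -> "AlignmentReport":
        return AlignmentReport(
            self.n_matched + other.n_matched,
            self.n_unmatched_obs + other.n_unmatched_obs,
            self.n_unmatched_epochs + other.n_unmatched_epochs,
            self.dropped_trailing_epochs + other.dropped_trailing_epochs,
        )


def merge_epochs(
    series: EpochSeries, target_length: int
) -> tuple[EpochSeries, int]:
    """Reintegrate epochs to a longer grid by summing constituent counts.

    ``target_length`` must be a positive integer multiple of the input
    epoch length. An incomplete trailing window is dropped (and reported),
    so total counts are conserved up to the dropped trailing epochs.

    Returns
    -------
    merged : EpochSeries
        Series on the ``target_length`` grid; window start times are the
        first constituent epoch's start time.
    n_dropped : int
        Number of trailing raw epochs that did not fill a whole window.
    """
    factor = target_length / series.epoch_length
    if factor != int(factor) or target_length <= 0:
        raise ValidationError(
            f"target epoch length {target_length}s is not a positive integer "
            f"multiple of the raw epoch length {series.epoch_length}s"
        )
    factor = int(factor)
    n_windows, n_dropped = divmod(len(series), factor)
    if n_windows == 0:
        raise ValidationError(
            f"series too short ({len(series)} epochs) for a {target_length}s window"
        )
    if n_dropped:
        logger.info(
            "dropping %d trailing epoch(s) not filling a %ds window (%s/%s)",
            n_dropped, target_length, series.participant_id, series.session_id,
        )
    kept = series.counts[: n_windows * factor]
    merged = EpochSeries(
        participant_id=series.participant_id,
        session_id=series.session_id,
        epoch_length=target_length,
        start_times=series.start_times[: n_windows * factor : factor],
        counts=kept.reshape(n_windows, factor).sum(axis=1),
    )
    return merged, n_dropped


def align(
    epochs: EpochSeries,
    obs: ObservationSeries,
    tolerance: float = DEFAULT_TOLERANCE_S,
) -> tuple[list[AlignedSample], AlignmentReport]:
    """Join 10-s epoch counts with DO codes interval-by-interval.

    Each observation interval is matched to the epoch whose start time lies
    within ``±tolerance`` seconds of the interval start; matched pairs become
    :class:`AlignedSample` rows with ``cpm = count × 60/interval_length``.
    Unmatched entries on either side are dropped pairwise and tallied — the
    protocol is silent on observer-missed intervals, and imputing counts or
    codes would contaminate the calibration.
    """
    if epochs.participant_id != obs.participant_id:
        raise ValidationError(
            f"cannot align different participants: "
            f"{epochs.participant_id!r} vs {obs.participant_id!r}"
        )
    if epochs.epoch_length != obs.interval_length:
        raise ValidationError(
            f"epoch length {epochs.epoch_length}s does not match observation "
            f"interval {obs.interval_length}s; merge_epochs() first"
        )
    scale = 60.0 / obs.interval_length
    epoch_times = epochs.start_times
    matched_epochs = np.zeros(len(epoch_times), dtype=bool)
    samples: list[AlignedSample] = []
    n_unmatched_obs = 0
    for i, t in enumerate(obs.interval_starts):
        lo = np.searchsorted(epoch_times, t - tolerance, side="left")
        hi = np.searchsorted(epoch_times, t + tolerance, side="right")
        if hi - lo > 1:
            raise AlignmentError(
                f"{hi - lo} epochs within ±{tolerance:g}s of interval start "
                f"t={t:g}: clock fault"
            )
        if hi == lo:
            n_unmatched_obs += 1
            continue
        matched_epochs[lo] = True
        count = float(epochs.counts[lo])
        samples.append(
            AlignedSample(
                participant_id=obs.participant_id,
                activity=obs.activities[i],
                role=obs.roles[i],
                interval_start=float(t),
                count_10s=count,
                cpm=count * scale,
                code=int(obs.codes[i]),
            )
        )
    report = AlignmentReport(
        n_matched=len(samples),
        n_unmatched_obs=n_unmatched_obs,
        n_unmatched_epochs=int((~matched_epochs).sum()),
    )
    if n_unmatched_obs or report.n_unmatched_epochs:
        logger.info(
            "alignment %s/%s: %d matched, %d observation interval(s) and "
            "%d epoch(s) unmatched",
            obs.participant_id, obs.session_id, report.n_matched,
            n_unmatched_obs, report.n_unmatched_epochs,
        )
    return samples, report
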