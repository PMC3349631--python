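"""Synthetic paired accelerometer/observation sessions.

No raw data accompany the calibration protocol, so this module generates
cohorts with the statistical structure the calibration assumes, making
every pipeline stage testable end to end:

* one SOFIT code per 10-s interval, drawn from an activity-specific code
  mixture with first-order persistence (probability ρ of repeating the
  previous code) to emulate the bouty, intermittent structure of
  children's activity;
* one counts·min⁻¹ value per interval, drawn from a code-conditional
  log-normal (counts are right-skewed); an optional point mass at a low
  count captures the near-zero floor of truly still sitting;
* the 10-s device count ``round(cpm/6)``, split into two 5-s epochs by
  symmetric binomial thinning, so the synthetic device stream exercises
  the same reintegration path as real 5-s exports.

The generating class boundaries — cpm midway between adjacent code
medians — are recorded as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import AlignmentReport, align, merge_epochs
from .datatypes import (
    CALIBRATION,
    CROSS_VALIDATION,
    ROLES,
    AlignedSample,
    EpochSeries,
    ObservationSeries,
)
from .exceptions import ValidationError


@dataclass(frozen=True)
class ActivityTemplate:
    """One protocol activity: its duration, code mixture and bout structure."""

    name: str
    duration_min: float
    code_mixture: dict[int, float]
    role: str
    persistence: float = 0.5

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if not 0.0 <= self.persistence < 1.0:
            raise ValidationError(f"persistence must be in [0, 1), got {self.persistence}")
        probs = np.array(list(self.code_mixture.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0) or np.any(probs < 0):
            raise ValidationError(f"{self.name}: code_mixture must be a distribution")
        if not set(self.code_mixture) <= {1, 2, 3, 4, 5}:
            raise ValidationError(f"{self.name}: codes must be SOFIT codes 1-5")


@dataclass(frozen=True)
class CountModel:
    """Code-conditional cpm distributions: log-normal with median per code.

    Medians must be non-decreasing in code and strictly increasing from
    code 3 upward (lying and sitting may share a floor). ``low_point_mass``
    is the probability that a code-1/2 interval emits ``point_mass_cpm``
    instead of a log-normal draw (zero-inflation of still sitting).
    """

    medians: dict[int, float] = field(
        default_factory=lambda: {1: 50.0, 2: 50.0, 3: 700.0, 4: 3000.0, 5: 6500.0}
    )
    sigma: float = 0.45
    low_point_mass: float = 0.0
    point_mass_cpm: float = 0.0

    def __post_init__(self) -> None:
        if set(self.medians) != {1, 2, 3, 4, 5}:
            raise ValidationError("medians must cover codes 1-5")
        m = [self.medians[c] for c in (1, 2, 3, 4, 5)]
        if not (m[0] <= m[1] < m[2] < m[3] < m[4]):
            raise ValidationError(
                f"medians must satisfy m1 <= m2 < m3 < m4 < m5, got {m}"
            )
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not 0.0 <= self.low_point_mass <= 1.0:
            raise ValidationError("low_point_mass must be a probability")

    def boundaries(self) -> dict[str, float]:
        """Generating class boundaries: cpm midway between flanking medians."""
        m = self.medians
        return {
            "sedentary": (m[2] + m[3]) / 2.0,
            "moderate": (m[3] + m[4]) / 2.0,
            "vigorous": (m[4] + m[5]) / 2.0,
        }


def default_templates() -> list[ActivityTemplate]:
    """The six-activity protocol menu.

    Durations follow the field protocol (10 min for the classroom and
    games activities, 5 min for the locomotor ones). Code mixtures reflect
    what a momentary-time-sampling observer records for each activity:
    drawing and DVD watching are almost entirely sitting; brisk walking is
    dominated by code 4 with some standing; jogging is nearly all code 5;
    the games activities mix standing, walking and vigorous play.
    """
    return [
        ActivityTemplate("drawing", 10, {1: 0.10, 2: 0.90}, CALIBRATION),
        ActivityTemplate("dvd", 10, {1: 0.15, 2: 0.85}, CROSS_VALIDATION),
        ActivityTemplate("walk", 5, {3: 0.20, 4: 0.78, 5: 0.02}, CALIBRATION),
        ActivityTemplate("jog", 5, {4: 0.05, 5: 0.95}, CALIBRATION),
        ActivityTemplate(
            "playground", 10, {2: 0.05, 3: 0.30, 4: 0.25, 5: 0.40}, CALIBRATION
        ),
        ActivityTemplate(
            "free_choice", 10, {2: 0.10, 3: 0.25, 4: 0.35, 5: 0.30}, CROSS_VALIDATION
        ),
    ]


@dataclass
class SimConfig:
    """Cohort-level simulation settings (defaults mirror the field study)."""

    n_participants: int = 28
    templates: Sequence[ActivityTemplate] = field(default_factory=default_templates)
    count_model: CountModel = field(default_factory=CountModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        roles = {t.role for t in self.templates}
        if not {CALIBRATION, CROSS_VALIDATION} <= roles:
            raise ValidationError(
                "templates must include at least one calibration and one "
                "cross-validation activity"
            )


def _sample_codes(template: ActivityTemplate, n: int, rng: np.random.Generator) -> np.ndarray:
    codes = np.array(sorted(template.code_mixture), dtype=np.int64)
    probs = np.array([template.code_mixture[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(codes, size=n, p=probs)
    if template.persistence > 0 and n > 1:
        repeat = rng.random(n) < template.persistence
        out = draws.copy()
        for i in range(1, n):
            if repeat[i]:
                out[i] = out[i - 1]
        return out
    return draws


def generate_session(
    participant_id: str,
    template: ActivityTemplate,
    model: CountModel,
    rng: np.random.Generator,
    interval_length: int = 10,
    epoch_length: int = 5,
    t0: float = 0.0,
) -> tuple[EpochSeries, ObservationSeries]:
    """One activity session: a 5-s epoch stream and its 10-s DO log."""
    n = int(round(template.duration_min * 60 / interval_length))
    codes = _sample_codes(template, n, rng)
    medians = np.array([model.medians[c] for c in codes], dtype=float)
    cpm = medians * np.exp(model.sigma * rng.standard_normal(n))
    if model.low_point_mass > 0:
        still = (codes <= 2) & (rng.random(n) < model.low_point_mass)
        cpm[still] = model.point_mass_cpm
    counts_10s = np.round(cpm * interval_length / 60.0).astype(np.int64)
    first_half = rng.binomial(counts_10s, 0.5)
    per_interval = interval_length // epoch_length
    if per_interval != 2 or interval_length % epoch_length:
        raise ValidationError("epoch split supports interval_length = 2 × epoch_length")
    epochs = np.empty(2 * n, dtype=np.int64)
    epochs[0::2] = first_half
    epochs[1::2] = counts_10s - first_half
    interval_starts = t0 + interval_length * np.arange(n, dtype=float)
    epoch_starts = t0 + epoch_length * np.arange(2 * n, dtype=float)
    session_id = f"{participant_id}_{template.name}"
    return (
        EpochSeries(participant_id, session_id, epoch_length, epoch_starts, epochs),
        ObservationSeries(
            participant_id,
            session_id,
            interval_length,
            interval_starts,
            codes,
            [template.name] * n,
            [template.role] * n,
        ),
    )


def generate_cohort(
    config: SimConfig,
) -> tuple[list[AlignedSample], dict, AlignmentReport]:
    """Simulate the whole cohort and push it through merge + align.

    Returns the pooled aligned samples (both roles), a ground-truth record
    (generating boundaries and model parameters) and the aggregate
    alignment report. Fully deterministic for a fixed config.
    """
    root = np.random.SeedSequence(config.seed)
    samples: list[AlignedSample] = []
    report = AlignmentReport()
    participant_seeds = root.spawn(config.n_participants)
    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        rng = np.random.default_rng(participant_seeds[p])
        for template in config.templates:
            raw_epochs, obs = generate_session(
                pid, template, config.count_model, rng
            )
            merged, _ = merge_epochs(raw_epochs, obs.interval_length)
            sess_samples, sess_report = align(merged, obs)
            samples.extend(sess_samples)
            report = report + sess_report
    ground_truth = {
        "boundaries_cpm": config.count_model.boundaries(),
        "medians_cpm": dict(config.count_model.medians),
        "sigma": config.count_model.sigma,
        "n_participants": config.n_participants,
        "seed": config.seed,
    }
    return samples, ground_truth, report
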