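"""CSV readers/writers for epoch, observation and aligned-sample tables.

CSV is the only interchange format: device vendors all export epoch counts
to CSV, and keeping the toolkit format-agnostic avoids a dependency on any
proprietary container. Timestamps are ISO-8601 in files and epoch seconds
in memory; timezone-naive inputs are assumed to share one clock (devices
and the observer's watch are synchronized in the field protocol).

Column names and the activity→role assignment differ between export
dialects, so both live in a :class:`Dialect` that can be loaded from a
YAML or JSON config file instead of being hard-coded.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CALIBRATION,
    CROSS_VALIDATION,
    ROLES,
    AlignedSample,
    EpochSeries,
    ObservationSeries,
    aligned_to_frame,
    frame_to_aligned,
)
from .exceptions import ValidationError

#: canonical activity menu and protocol role of each activity
DEFAULT_ACTIVITY_ROLES: dict[str, str] = {
    "drawing": CALIBRATION,
    "walk": CALIBRATION,
    "jog": CALIBRATION,
    "playground": CALIBRATION,
    "dvd": CROSS_VALIDATION,
    "free_choice": CROSS_VALIDATION,
}

#: common spellings seen in observation logs, mapped to canonical names
_ACTIVITY_ALIASES: dict[str, str] = {
    "drawing": "drawing",
    "drawing coloring": "drawing",
    "coloring": "drawing",
    "colouring": "drawing",
    "dvd": "dvd",
    "dvd watching": "dvd",
    "dvd viewing": "dvd",
    "walk": "walk",
    "walking": "walk",
    "brisk walking": "walk",
    "self paced brisk walking": "walk",
    "jog": "jog",
    "jogging": "jog",
    "self paced jogging": "jog",
    "playground": "playground",
    "playground games": "playground",
    "free_choice": "free_choice",
    "free choice": "free_choice",
    "free choice games": "free_choice",
    "free play": "free_choice",
}


def normalize_activity(label: str) -> str:
    """Collapse a free-text activity label to its canonical menu name.

    Unknown labels are returned lower-cased with punctuation collapsed so
    the caller can decide whether to reject them.
    """
    key = re.sub(r"[^a-z0-9]+", " ", str(label).lower()).strip()
    return _ACTIVITY_ALIASES.get(key, key.replace(" ", "_"))


@dataclass
class Dialect:
    """Column mapping and activity→role assignment for one CSV dialect."""

    timestamp_col: str = "timestamp"
    counts_col: str = "counts"
    code_col: str = "code"
    activity_col: str = "activity"
    participant_col: str = "participant"
    activity_roles: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_ROLES)
    )
    #: if True, unknown activities default to calibration instead of erroring
    permissive_activities: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: Mapping) -> "Dialect":
        kwargs = {}
        columns = data.get("columns", {})
        for key in ("timestamp", "counts", "code", "activity", "participant"):
            if key in columns:
                kwargs[f"{key}_col"] = str(columns[key])
        if "activity_roles" in data:
            roles = {
                normalize_activity(k): str(v) for k, v in data["activity_roles"].items()
            }
            for act, role in roles.items():
                if role not in ROLES:
                    raise ValidationError(
                        f"activity {act!r} mapped to unknown role {role!r}"
                    )
            kwargs["activity_roles"] = roles
        if "permissive_activities" in data:
            kwargs["permissive_activities"] = bool(data["permissive_activities"])
        return cls(**kwargs)


def _parse_times(column: pd.Series, path: Path) -> np.ndarray:
    """ISO-8601 strings or plain numbers -> seconds on a shared clock."""
    numeric = pd.to_numeric(column, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    try:
        parsed = pd.to_datetime(column, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparsable timestamp column: {exc}") from exc
    return parsed.astype("int64").to_numpy() / 1e9


def read_epochs(
    path: str | Path,
    epoch_length: int = 5,
    dialect: Dialect | None = None,
    participant_id: str = "",
    session_id: str = "",
) -> EpochSeries:
    """Read an accelerometer epoch CSV into an :class:`EpochSeries`.

    Rows whose count field is non-numeric are dropped; negative counts and
    irregular epoch spacing raise :class:`ValidationError`.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    table = pd.read_csv(path)
    for col in (dialect.timestamp_col, dialect.counts_col):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    counts = pd.to_numeric(table[dialect.counts_col], errors="coerce")
    keep = counts.notna()
    table = table.loc[keep]
    if len(table) == 0:
        raise ValidationError(f"{path}: no epochs")
    return EpochSeries(
        participant_id=participant_id or str(path.stem),
        session_id=session_id or str(path.stem),
        epoch_length=epoch_length,
        start_times=_parse_times(table[dialect.timestamp_col], path),
        counts=counts.loc[keep].to_numpy(),
    )


def write_epochs(series: EpochSeries, path: str | Path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    pd.DataFrame(
        {
            dialect.timestamp_col: _format_times(series.start_times),
            dialect.counts_col: series.counts,
        }
    ).to_csv(path, index=False)


def read_observations(
    path: str | Path,
    interval_length: int = 10,
    dialect: Dialect | None = None,
    session_id: str = "",
) -> ObservationSeries:
    """Read a direct-observation log CSV into an :class:`ObservationSeries`.

    Activity labels are normalized to the configured menu and each row's
    role (calibration vs. cross-validation) is assigned from the dialect's
    activity→role map. Unknown activities raise unless the dialect is
    permissive, in which case they default to calibration.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    table = pd.read_csv(path)
    for col in (dialect.timestamp_col, dialect.code_col, dialect.activity_col):
        if col not in table.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    codes = pd.to_numeric(table[dialect.code_col], errors="coerce")
    if codes.isna().any():
        row = int(codes.index[codes.isna()][0]) + 2  # header + 1-based
        raise ValidationError(f"{path}: non-numeric code at file row {row}")
    bad = ~codes.isin([1, 2, 3, 4, 5])
    if bad.any():
        row = int(codes.index[bad][0]) + 2
        raise ValidationError(
            f"{path}: code {codes[bad].iloc[0]:g} out of range 1-5 at file row {row}"
        )
    activities = [normalize_activity(a) for a in table[dialect.activity_col]]
    roles = []
    for i, act in enumerate(activities):
        role = dialect.activity_roles.get(act)
        if role is None:
            if dialect.permissive_activities:
                role = CALIBRATION
            else:
                raise ValidationError(
                    f"{path}: unknown activity {act!r} at file row {i + 2}; "
                    "add it to the dialect's activity_roles map"
                )
        roles.append(role)
    if dialect.participant_col in table.columns:
        pids = table[dialect.participant_col].astype(str).unique()
        if len(pids) > 1:
            raise ValidationError(f"{path}: multiple participants in one file: {pids}")
        participant_id = pids[0]
    else:
        participant_id = str(path.stem)
    return ObservationSeries(
        participant_id=participant_id,
        session_id=session_id or str(path.stem),
        interval_length=interval_length,
        interval_starts=_parse_times(table[dialect.timestamp_col], path),
        codes=codes.to_numpy(),
        activities=activities,
        roles=roles,
    )


def write_observations(
    series: ObservationSeries, path: str | Path, dialect: Dialect | None = None
) -> None:
    dialect = dialect or Dialect()
    pd.DataFrame(
        {
            dialect.timestamp_col: _format_times(series.interval_starts),
            dialect.code_col: series.codes,
            dialect.activity_col: series.activities,
            dialect.participant_col: series.participant_id,
        }
    ).to_csv(path, index=False)


def write_aligned(samples: Iterable[AlignedSample], path: str | Path) -> None:
    """Write aligned samples to CSV (columns fixed, full float precision)."""
    aligned_to_frame(samples).to_csv(path, index=False)


def read_aligned(path: str | Path) -> list[AlignedSample]:
    frame = pd.read_csv(path)
    required = {"participant", "activity", "role", "interval_start", "count_10s", "cpm", "code"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: aligned CSV missing columns {sorted(missing)}")
    return frame_to_aligned(frame)


def _format_times(times: np.ndarray) -> list[str]:
    stamps = pd.to_datetime(np.round(np.asarray(times, dtype=float) * 1e9).astype("int64"))
    return [t.isoformat() for t in stamps]
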