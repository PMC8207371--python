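"""Reading, validating, and windowing raw detection logs and site metadata.

The on-disk dialect is deliberately plain: a detection log is a CSV with
header ``timestamp,tag_id,antenna_id`` and ISO-8601 local wall-clock
timestamps; the antenna registry is ``antenna_id,roost_id,role`` with
role in {entry, ceiling}; the tag registry is ``tag_id,cohort_year``.
Timestamps carry no time zone — single-site logs are treated as
site-local throughout.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ENTRY = "entry"
CEILING = "ceiling"
_ROLES = frozenset({ENTRY, CEILING})


@dataclass(frozen=True, order=True)
class DetectionEvent:
    """One tag read: when, which tag, which antenna."""

    timestamp: dt.datetime
    tag_id: str
    antenna_id: str


@dataclass(frozen=True)
class AntennaRegistry:
    """Maps each antenna to its roost and role (entry vs ceiling).

    Entry antennas sit over roost entryways and record passages; ceiling
    antennas sit on attic ceilings and record roosting presence. The two
    roles feed different networks downstream and are never mixed.
    """

    roost_of: dict[str, str]
    role_of: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.roost_of) != set(self.role_of):
            raise ValueError("roost_of and role_of must cover the same antennas")
        bad = {a: r for a, r in self.role_of.items() if r not in _ROLES}
        if bad:
            raise ValueError(f"invalid antenna role(s): {bad}; must be one of {sorted(_ROLES)}")

    @property
    def antenna_ids(self) -> frozenset[str]:
        return frozenset(self.roost_of)

    def antennas_with_role(self, role: str) -> frozenset[str]:
        return frozenset(a for a, r in self.role_of.items() if r == role)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AntennaRegistry":
        required = {"antenna_id", "roost_id", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"antenna registry missing columns: {sorted(missing)}")
        if df["antenna_id"].duplicated().any():
            dups = df.loc[df["antenna_id"].duplicated(), "antenna_id"].tolist()
            raise ValueError(f"duplicate antenna_id(s): {dups}")
        return cls(
            roost_of=dict(zip(df["antenna_id"].astype(str), df["roost_id"].astype(str))),
            role_of=dict(zip(df["antenna_id"].astype(str), df["role"].astype(str))),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "AntennaRegistry":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.roost_of)
        return pd.DataFrame(
            {
                "antenna_id": rows,
                "roost_id": [self.roost_of[a] for a in rows],
                "role": [self.role_of[a] for a in rows],
            }
        )


@dataclass(frozen=True)
class TagRegistry:
    """Maps each PIT tag to the cohort year it was implanted."""

    cohort_of: dict[str, int]

    @classmethod
    def read_csv(cls, path: str | Path) -> "TagRegistry":
        df = pd.read_csv(path, dtype={"tag_id": str, "cohort_year": int})
        if df["tag_id"].duplicated().any():
            dups = df.loc[df["tag_id"].duplicated(), "tag_id"].tolist()
            raise ValueError(f"duplicate tag_id(s): {dups}")
        return cls(cohort_of=dict(zip(df["tag_id"], df["cohort_year"])))

    def to_frame(self) -> pd.DataFrame:
        tags = sorted(self.cohort_of)
        return pd.DataFrame({"tag_id": tags, "cohort_year": [self.cohort_of[t] for t in tags]})


@dataclass(frozen=True)
class StudyWindow:
    """Inclusive date range of the analysis, e.g. a maternity season.

    ``day_rollover_hour`` sets where one "roost-day" ends and the next
    begins: an event's roost-day is the calendar date after subtracting
    that many hours. The default 0 makes a roost-day a plain calendar
    date; a nonzero value lets nocturnal activity spanning midnight be
    attributed to a single night.
    """

    start_date: dt.date
    end_date: dt.date
    day_rollover_hour: int = 0

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("start_date must be <= end_date")
        if not 0 <= self.day_rollover_hour <= 23:
            raise ValueError("day_rollover_hour must be in 0..23")

    def roost_day(self, ts: dt.datetime) -> dt.date:
        """Calendar date of the roost-day containing ``ts``."""
        return (ts - dt.timedelta(hours=self.day_rollover_hour)).date()

    def roost_day_midnight(self, ts: dt.datetime) -> dt.datetime:
        """Start instant of the roost-day containing ``ts``."""
        day = self.roost_day(ts)
        return dt.datetime.combine(day, dt.time()) + dt.timedelta(hours=self.day_rollover_hour)

    def contains(self, ts: dt.datetime) -> bool:
        return self.start_date <= self.roost_day(ts) <= self.end_date

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(self.n_days)]


def _parse_timestamp(raw: str) -> dt.datetime:
    return dt.datetime.fromisoformat(raw.strip())


def read_detections(
    path: str | Path,
    registry: AntennaRegistry | None = None,
    strict: bool = False,
    counters: dict | None = None,
) -> list[DetectionEvent]:
    """Parse a detection-log CSV into events, in file order.

    In strict mode a malformed timestamp or an antenna absent from the
    registry aborts with the offending row number; in non-strict mode
    such rows are dropped, counted in the log, and tallied into
    ``counters`` (keys ``malformed_timestamp`` and ``unknown_antenna``)
    when a dict is passed. Duplicate identical rows are retained — 4 Hz
    scanners legitimately emit repeats, and downstream binning
    deduplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    required = {"timestamp", "tag_id", "antenna_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detection log missing columns: {sorted(missing)}")

    known = registry.antenna_ids if registry is not None else None
    events: list[DetectionEvent] = []
    n_bad_ts = 0
    n_unknown = 0
    for i, (raw_ts, tag, ant) in enumerate(
        zip(df["timestamp"], df["tag_id"], df["antenna_id"]), start=2
    ):
        try:
            ts = _parse_timestamp(str(raw_ts))
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {i}: malformed timestamp {raw_ts!r}") from exc
            n_bad_ts += 1
            continue
        ant = str(ant)
        if known is not None and ant not in known:
            if strict:
                raise ValueError(f"row {i}: unknown antenna {ant!r}")
            n_unknown += 1
            continue
        events.append(DetectionEvent(ts, str(tag), ant))
    if n_bad_ts or n_unknown:
        logger.warning(
            "read_detections(%s): skipped %d malformed-timestamp and %d unknown-antenna rows",
            path,
            n_bad_ts,
            n_unknown,
        )
    if counters is not None:
        counters["malformed_timestamp"] = n_bad_ts
        counters["unknown_antenna"] = n_unknown
    return events


def write_detections(events: Iterable[DetectionEvent], path: str | Path) -> None:
    """Write events to the detection-log CSV dialect (ISO-8601, file order)."""
    df = events_frame(events)
    df.to_csv(path, index=False)


def events_frame(events: Iterable[DetectionEvent]) -> pd.DataFrame:
    """Events as a DataFrame with columns timestamp, tag_id, antenna_id."""
    rows = [(e.timestamp.isoformat(sep=" "), e.tag_id, e.antenna_id) for e in events]
    return pd.DataFrame(rows, columns=["timestamp", "tag_id", "antenna_id"])


def filter_window(
    events: Sequence[DetectionEvent], window: StudyWindow
) -> list[DetectionEvent]:
    """Keep events whose roost-day falls inside the window; stable order."""
    return [e for e in events if window.contains(e.timestamp)]
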