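"""Telemetry screening: animal- and fix-level inclusion rules and subsampling.

Raw collar relocations are filtered before habitat modeling so that the
presence sample reflects resident adults with adequately precise, temporally
representative fixes:

* capture and mortality records are removed (behaviour around handling or
  death is not habitat selection);
* GPS fixes with a low-quality fix status or a position dilution of
  precision (DOP) above a cutoff are removed;
* whole animals are removed when they are juveniles, have too few retained
  locations in any 12-month window, or their locations span too few distinct
  calendar months within every 12-month window;
* GPS tracks are subsampled to a minimum spacing (default one fix every
  5 h) to reduce serial autocorrelation relative to sparse VHF data.

The 12-month window is evaluated as a sliding 365-day window anchored at
each retained fix, the stricter reading of a "12-month period".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VHF = "VHF"
GPS = "GPS"

_EVENTS = ("normal", "capture", "mortality")


@dataclass(frozen=True)
class TelemetryFix:
    """One relocation with its quality metadata."""

    animal_id: str
    timestamp: datetime
    x: float
    y: float
    collar: str = GPS
    dop: float = float("nan")
    fix_status: str = "3D"
    event: str = "normal"
    age_years: float = 5.0

    def __post_init__(self) -> None:
        if self.event not in _EVENTS:
            raise ValueError(f"unknown event {self.event!r}")
        if not np.isnan(self.dop) and self.dop < 0:
            raise ValueError("dop must be non-negative")


@dataclass
class ScreeningConfig:
    """Inclusion rules. Defaults follow the resident-adult screening design."""

    min_age_years: float = 4.0
    min_fixes: int = 30
    window_months: int = 12
    min_distinct_months: int = 3
    max_dop: float = 7.0
    subsample_hours: float = 5.0
    low_quality_status: frozenset = frozenset({"2D", "failed"})

    def __post_init__(self) -> None:
        for name in ("min_age_years", "min_fixes", "window_months",
                     "min_distinct_months", "max_dop", "subsample_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_distinct_months > 12:
            raise ValueError("min_distinct_months must be <= 12")


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["animal_id", "timestamp", "x", "y", "collar", "dop",
                "fix_status", "event", "age_years"]


def fixes_to_frame(fixes: Iterable[TelemetryFix]) -> pd.DataFrame:
    rows = [
        (f.animal_id, f.timestamp.isoformat(), f.x, f.y, f.collar, f.dop,
         f.fix_status, f.event, f.age_years)
        for f in fixes
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_fixes(frame: pd.DataFrame) -> list[TelemetryFix]:
    fixes = []
    for idx, row in frame.iterrows():
        try:
            ts = pd.Timestamp(row["timestamp"])
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"unparseable timestamp {row['timestamp']!r} in record {idx}"
            ) from exc
        fixes.append(
            TelemetryFix(
                animal_id=str(row["animal_id"]),
                timestamp=ts.to_pydatetime(),
                x=float(row["x"]),
                y=float(row["y"]),
                collar=str(row["collar"]),
                dop=float(row["dop"]) if pd.notna(row["dop"]) else float("nan"),
                fix_status=str(row["fix_status"]),
                event=str(row["event"]),
                age_years=float(row["age_years"]),
            )
        )
    return fixes


def write_fixes_csv(fixes: Iterable[TelemetryFix], path: str | Path) -> None:
    fixes_to_frame(fixes).to_csv(path, index=False)


def read_fixes_csv(path: str | Path) -> list[TelemetryFix]:
    return frame_to_fixes(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _sorted_fixes(fixes: Sequence[TelemetryFix]) -> list[TelemetryFix]:
    # Internal sort makes screening independent of input ordering.
    return sorted(fixes, key=lambda f: (f.animal_id, f.timestamp, f.x, f.y))


def screen_fixes(
    fixes: Sequence[TelemetryFix], config: ScreeningConfig | None = None
) -> tuple[list[TelemetryFix], pd.DataFrame]:
    """Apply fix-level then animal-level inclusion rules.

    Returns the retained fixes and a rejection log with one row per removed
    fix (stage ``fix``) or per removed animal (stage ``animal``).
    """
    if len(fixes) == 0:
        raise ValueError("no fixes supplied")
    config = config or ScreeningConfig()
    fixes = _sorted_fixes(fixes)

    log_rows: list[tuple[str, str, str]] = []
    retained: list[TelemetryFix] = []
    for f in fixes:
        if f.event in ("capture", "mortality"):
            log_rows.append((f"{f.animal_id}@{f.timestamp.isoformat()}", "fix",
                             f"event:{f.event}"))
            continue
        if f.collar == GPS:
            if f.fix_status in config.low_quality_status:
                log_rows.append((f"{f.animal_id}@{f.timestamp.isoformat()}",
                                 "fix", "fix_status"))
                continue
            if not np.isnan(f.dop) and f.dop > config.max_dop:
                log_rows.append((f"{f.animal_id}@{f.timestamp.isoformat()}",
                                 "fix", f"dop>{config.max_dop}"))
                continue
        retained.append(f)

    window = timedelta(days=365)
    kept: list[TelemetryFix] = []
    by_animal: dict[str, list[TelemetryFix]] = {}
    for f in retained:
        by_animal.setdefault(f.animal_id, []).append(f)

    for animal_id, track in by_animal.items():
        age = max(f.age_years for f in track)
        if age < config.min_age_years:
            log_rows.append((animal_id, "animal", "age"))
            continue
        times = [f.timestamp for f in track]
        counts = []
        month_counts = []
        for i, t0 in enumerate(times):
            in_window = [t for t in times[i:] if t - t0 < window]
            counts.append(len(in_window))
            month_counts.append(len({(t.year, t.month) for t in in_window}))
        if max(counts) < config.min_fixes:
            log_rows.append((animal_id, "animal", "window_fixes"))
            continue
        if max(month_counts) < config.min_distinct_months:
            log_rows.append((animal_id, "animal", "distinct_months"))
            continue
        kept.extend(track)

    log = pd.DataFrame(log_rows, columns=["record", "stage", "reason"])
    return _sorted_fixes(kept), log


def subsample_track(
    fixes: Sequence[TelemetryFix], interval_hours: float
) -> list[TelemetryFix]:
    """Greedy temporal thinning of a single animal's GPS fixes.

    Keeps the first GPS fix, then the earliest fix at least ``interval_hours``
    after the last kept one. VHF fixes pass through untouched (their sampling
    is already sparse and irregular). Output is a subsequence of the input.
    """
    if len(fixes) == 0:
        return []
    animals = {f.animal_id for f in fixes}
    if len(animals) > 1:
        raise ValueError("subsample_track expects fixes of a single animal")
    ordered = sorted(fixes, key=lambda f: f.timestamp)
    interval = timedelta(hours=interval_hours)
    kept: list[TelemetryFix] = []
    last_gps: datetime | None = None
    for f in ordered:
        if f.collar != GPS:
            kept.append(f)
            continue
        if last_gps is None or f.timestamp - last_gps >= interval:
            kept.append(f)
            last_gps = f.timestamp
    return kept


def subsample_all(
    fixes: Sequence[TelemetryFix], interval_hours: float
) -> list[TelemetryFix]:
    """Apply :func:`subsample_track` per animal and re-merge."""
    by_animal: dict[str, list[TelemetryFix]] = {}
    for f in fixes:
        by_animal.setdefault(f.animal_id, []).append(f)
    out: list[TelemetryFix] = []
    for track in by_animal.values():
        out.extend(subsample_track(track, interval_hours))
    return _sorted_fixes(out)
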