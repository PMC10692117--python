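"""Space-time segmentation of the event table.

The analysis partitions events into three historically meaningful periods
(1989-1999 peace-negotiation era, 2000-2009 military-offensive era,
2010-2018 de-escalation era) crossed with three spatial scopes: the whole
country, seven regions built from the overlap of the main actors'
organisational structures, and the administrative departments.  Each
(scope, unit, period) cell — a *segment* — yields the list of event
severities on which the power law is fitted.
"""

from __future__ import annotations

import datetime as dt
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .io_ged import ConflictEvent


@dataclass(frozen=True)
class PeriodDef:
    label: str
    start: dt.date
    end: dt.date  # inclusive


#: calendar-year period boundaries, inclusive at both ends
DEFAULT_PERIODS = (
    PeriodDef("P1", dt.date(1989, 1, 1), dt.date(1999, 12, 31)),
    PeriodDef("P2", dt.date(2000, 1, 1), dt.date(2009, 12, 31)),
    PeriodDef("P3", dt.date(2010, 1, 1), dt.date(2018, 12, 31)),
)

ALL_PERIOD = "ALL"
COUNTRY_UNIT = "ALL"


class PeriodError(ValueError):
    """Date outside every configured period."""


class SegmentKey(NamedTuple):
    scope: str  # country | region | department
    unit: str  # region id (as str), department name, or "ALL"
    period: str  # P1 | P2 | P3 | ALL


def normalize_department(name: str) -> str:
    """Case-fold and strip accents so 'Bogotá' and 'BOGOTA' match."""
    decomposed = unicodedata.normalize("NFKD", name.strip())
    return "".join(c for c in decomposed if not unicodedata.combining(c)).casefold()


def assign_period(date: dt.date, periods=DEFAULT_PERIODS) -> str:
    """Map a date to its period label; boundaries inclusive on both ends."""
    for p in periods:
        if p.start <= date <= p.end:
            return p.label
    raise PeriodError(f"{date.isoformat()} falls outside every period")


class RegionMap:
    """Department -> region lookup with accent/case-insensitive matching."""

    def __init__(self, regions: dict[int, list[str]], labels: dict[int, str] | None = None):
        self.regions = {int(k): list(v) for k, v in regions.items()}
        self.labels = {int(k): v for k, v in (labels or {}).items()}
        self._lookup: dict[str, int] = {}
        for rid, depts in self.regions.items():
            for d in depts:
                key = normalize_department(d)
                if key in self._lookup and self._lookup[key] != rid:
                    raise ValueError(f"department {d!r} assigned to two regions")
                self._lookup[key] = rid

    @classmethod
    def from_yaml(cls, path) -> "RegionMap":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(cfg["regions"], cfg.get("labels"))

    @classmethod
    def default(cls) -> "RegionMap":
        ref = resources.files("conflict_spectroscopy").joinpath("data/regions_default.yaml")
        with resources.as_file(ref) as p:
            return cls.from_yaml(p)

    def region_of(self, department: str) -> int | None:
        return self._lookup.get(normalize_department(department))

    @property
    def departments(self) -> list[str]:
        return [d for depts in self.regions.values() for d in depts]


@dataclass
class SegmentedData:
    """Severity lists per segment, plus the unmapped-department report.

    Events whose department is not in the region map are excluded from
    region-scope segments only; they still count at country and
    department scope.
    """

    segments: dict[SegmentKey, np.ndarray]
    unmapped_departments: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[SegmentKey, int]:
        return {k: int(v.size) for k, v in self.segments.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per event per (scope, unit, period) cell."""
        rows = []
        for key, sev in sorted(self.segments.items()):
            for s in sev:
                rows.append((key.scope, key.unit, key.period, int(s)))
        return pd.DataFrame(rows, columns=["segment_scope", "unit", "period", "fatalities"])


def segment_events(
    events: list[ConflictEvent],
    region_map: RegionMap,
    periods=DEFAULT_PERIODS,
) -> SegmentedData:
    """Build every (scope, unit, period) severity list.

    Each event lands in exactly one (region, period) cell (if its
    department is mapped) and one (department, period) cell; the ALL
    period and country scope are unions of those.
    """
    per_cell: dict[SegmentKey, list[int]] = {}
    unmapped: dict[str, int] = {}

    def add(scope: str, unit: str, period: str, x: int) -> None:
        per_cell.setdefault(SegmentKey(scope, unit, period), []).append(x)

    for ev in events:
        period = assign_period(ev.date, periods)
        x = ev.fatalities
        add("country", COUNTRY_UNIT, period, x)
        add("country", COUNTRY_UNIT, ALL_PERIOD, x)
        dept = ev.department
        add("department", dept, period, x)
        add("department", dept, ALL_PERIOD, x)
        rid = region_map.region_of(dept)
        if rid is None:
            unmapped[dept] = unmapped.get(dept, 0) + 1
        else:
            add("region", str(rid), period, x)
            add("region", str(rid), ALL_PERIOD, x)

    segments = {k: np.asarray(v, dtype=np.int64) for k, v in per_cell.items()}
    return SegmentedData(segments=segments, unmapped_departments=unmapped)
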