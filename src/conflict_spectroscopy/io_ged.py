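"""Ingestion and filtering of GED-like conflict-event tables.

Events come as a CSV with one row per violent event (date, administrative
department, actor dyad, best fatality estimate, geo-precision code in the
UCDP "where_prec" sense).  A column-name mapping binds real UCDP GED
headers ("best", "where_prec", "adm_1", ...) to the canonical fields
without code changes.  Filtering keeps events with at least one battle
death, a geo-precision good enough to place the event in a department
(code <= 4), an actor dyad drawn from the study's whitelist, and a date
inside the study window.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field

import yaml

#: canonical field -> default UCDP GED column name
DEFAULT_SCHEMA = {
    "event_id": "id",
    "date": "date_start",
    "department": "adm_1",
    "fatalities": "best",
    "side_a": "side_a",
    "side_b": "side_b",
    "geo_precision": "where_prec",
}

STUDY_START = dt.date(1989, 1, 1)
STUDY_END = dt.date(2018, 12, 31)


class SchemaError(ValueError):
    """A mapped column is missing from the CSV header."""


class EmptyInputError(ValueError):
    """The CSV contains no data rows."""


class ConfigError(ValueError):
    """Invalid filter configuration (e.g. empty actor whitelist)."""


@dataclass(frozen=True)
class ConflictEvent:
    """One dated, located, actor-attributed fatality count."""

    event_id: str
    date: dt.date
    department: str
    fatalities: int
    side_a: str
    side_b: str
    geo_precision: int


@dataclass(frozen=True)
class RowError:
    """Per-row ingestion diagnostic (row number is 1-based, data rows)."""

    row: int
    field: str
    message: str


@dataclass
class ReadResult:
    events: list[ConflictEvent]
    rejected: list[RowError]


@dataclass(frozen=True)
class FilterConfig:
    actor_whitelist: frozenset[str]
    min_fatalities: int = 1
    max_geo_precision: int = 4
    date_range: tuple[dt.date, dt.date] = (STUDY_START, STUDY_END)

    def __post_init__(self):
        if not self.actor_whitelist:
            raise ConfigError("actor whitelist must not be empty")
        if self.min_fatalities < 1:
            raise ConfigError("min_fatalities must be >= 1")
        if not 1 <= self.max_geo_precision <= 7:
            raise ConfigError("max_geo_precision must be in 1..7")


@dataclass
class FilterAudit:
    """Per-criterion removal counts (criteria are conjunctive, so counts
    are order-independent; an event violating several criteria increments
    each of them)."""

    n_input: int = 0
    n_kept: int = 0
    removed_fatalities: int = 0
    removed_geo_precision: int = 0
    removed_actors: int = 0
    removed_date: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def load_schema(path) -> dict:
    """Load a canonical-field -> column-name mapping from YAML/JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    schema = dict(DEFAULT_SCHEMA)
    schema.update(mapping or {})
    return schema


def read_events(path, schema_config: dict | None = None) -> ReadResult:
    """Parse a GED-like CSV into ConflictEvents.

    Rows with an unparseable date, a non-integer fatality count, or a bad
    geo-precision code are rejected with a per-row diagnostic rather than
    silently dropped.  A missing mapped column raises SchemaError naming
    the column; a file without data rows raises EmptyInputError.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)

    events: list[ConflictEvent] = []
    rejected: list[RowError] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for fld, col in schema.items():
            if col not in header:
                raise SchemaError(f"mapped column {col!r} (field {fld!r}) not in header")
        n_rows = 0
        for i, row in enumerate(reader, start=1):
            n_rows += 1
            try:
                date = dt.date.fromisoformat(row[schema["date"]].strip()[:10])
            except ValueError:
                rejected.append(RowError(i, "date", f"unparseable date {row[schema['date']]!r}"))
                continue
            raw_fat = row[schema["fatalities"]].strip()
            try:
                fatalities = int(raw_fat)
            except ValueError:
                rejected.append(RowError(i, "fatalities", f"non-integer fatalities {raw_fat!r}"))
                continue
            raw_prec = row[schema["geo_precision"]].strip()
            try:
                geo_precision = int(raw_prec)
            except ValueError:
                rejected.append(RowError(i, "geo_precision", f"non-integer code {raw_prec!r}"))
                continue
            events.append(
                ConflictEvent(
                    event_id=row[schema["event_id"]],
                    date=date,
                    department=row[schema["department"]],
                    fatalities=fatalities,
                    side_a=row[schema["side_a"]],
                    side_b=row[schema["side_b"]],
                    geo_precision=geo_precision,
                )
            )
    if n_rows == 0:
        raise EmptyInputError(f"{path}: no data rows")
    return ReadResult(events=events, rejected=rejected)


def filter_events(
    events: list[ConflictEvent], cfg: FilterConfig
) -> tuple[list[ConflictEvent], FilterAudit]:
    """Apply the study's selection criteria conjunctively.

    Kept events have fatalities >= min, geo-precision <= max, a dyad
    {side_a, side_b} contained in the actor whitelist, and a date inside
    the study window.
    """
    audit = FilterAudit(n_input=len(events))
    lo, hi = cfg.date_range
    kept = []
    for ev in events:
        ok = True
        if ev.fatalities < cfg.min_fatalities:
            audit.removed_fatalities += 1
            ok = False
        if ev.geo_precision > cfg.max_geo_precision:
            audit.removed_geo_precision += 1
            ok = False
        if not {ev.side_a, ev.side_b} <= cfg.actor_whitelist:
            audit.removed_actors += 1
            ok = False
        if not lo <= ev.date <= hi:
            audit.removed_date += 1
            ok = False
        if ok:
            kept.append(ev)
    audit.n_kept = len(kept)
    return kept, audit


def write_events_csv(events: list[ConflictEvent], path) -> None:
    """Export canonical events (the dialect read_events reads back)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DEFAULT_SCHEMA.values())
        for ev in events:
            w.writerow(
                [ev.event_id, ev.date.isoformat(), ev.department, ev.fatalities,
                 ev.side_a, ev.side_b, ev.geo_precision]
            )
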