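"""Synthetic GED-like event tables with known ground truth.

Every pipeline stage (ingestion, filtering, segmentation, fitting, GOF,
subsampling) is testable without the real event dataset: the generator
emits a raw CSV-shaped table whose per-segment severity distributions,
planted filter violations, and exact row counts are all recorded in a
manifest.  Severities are a mixture of a sub-threshold "body" (truncated
geometric on {1..xmin-1}, which produces the concave sub-xmin shoulder
seen in empirical severity CCDFs) and a discrete power-law tail with the
planned (alpha, xmin).

What the generator does *not* emulate: actor-dyad frequencies beyond
populating the columns, within-period event timing (dates are uniform in
the period), and spatial coordinates.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gof import sample_discrete_pl
from .segmentation import DEFAULT_PERIODS, PeriodDef, RegionMap

DEFAULT_ACTOR_POOL = (
    ("Government of Colombia", "FARC"),
    ("Government of Colombia", "ELN"),
    ("Government of Colombia", "AUC"),
    ("FARC", "AUC"),
)


class SpecError(ValueError):
    """Invalid synthetic specification (e.g. unknown department)."""


@dataclass(frozen=True)
class SegmentPlan:
    """Ground-truth plan for one (department, period) cell."""

    department: str
    period: str  # P1 | P2 | P3
    n_events: int
    alpha_true: float
    xmin_true: int = 1
    body_fraction: float = 0.0  # probability of a sub-xmin "body" draw
    body_geom_p: float = 0.5  # truncated-geometric success probability

    def __post_init__(self):
        if self.n_events < 1:
            raise SpecError("n_events must be >= 1 per planned segment")
        if not 0 <= self.body_fraction < 1:
            raise SpecError("body_fraction must lie in [0, 1)")
        if self.body_fraction > 0 and self.xmin_true < 2:
            raise SpecError("a body requires xmin_true >= 2")


@dataclass
class SyntheticSpec:
    segments: list[SegmentPlan]
    n_geo_violations: int = 0  # planted rows with geo_precision > 4
    n_zero_fatalities: int = 0  # planted rows with fatalities = 0
    actor_pool: tuple = DEFAULT_ACTOR_POOL
    seed: int = 0


def _sample_body(plan: SegmentPlan, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated geometric on {1 .. xmin-1}."""
    support = np.arange(1, plan.xmin_true)
    w = (1 - plan.body_geom_p) ** (support - 1)
    return rng.choice(support, size=n, p=w / w.sum())


def _period_bounds(label: str, periods=DEFAULT_PERIODS) -> PeriodDef:
    for p in periods:
        if p.label == label:
            return p
    raise SpecError(f"unknown period label {label!r}")


def generate_event_table(
    spec: SyntheticSpec,
    region_map: RegionMap | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Emit raw rows (the CSV dialect the reader ingests) plus a manifest.

    Segment severities mix body and tail draws per plan; dates are
    uniform within the period; planted geo-precision and zero-fatality
    violations are appended at the end.  The manifest records every
    ground-truth parameter and the exact planted counts, so every
    downstream filter/segment count is predictable by integer equality.
    """
    region_map = region_map or RegionMap.default()
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []
    manifest_segments = []
    eid = 0

    for plan in spec.segments:
        if region_map.region_of(plan.department) is None:
            raise SpecError(f"department {plan.department!r} not in the region map")
        period = _period_bounds(plan.period)
        n_body = int(rng.binomial(plan.n_events, plan.body_fraction))
        n_tail = plan.n_events - n_body
        sev = np.concatenate(
            [
                _sample_body(plan, n_body, rng) if n_body else np.empty(0, np.int64),
                sample_discrete_pl(plan.alpha_true, plan.xmin_true, n_tail, rng),
            ]
        )
        rng.shuffle(sev)
        span = (period.end - period.start).days
        offsets = rng.integers(0, span + 1, size=plan.n_events)
        for k in range(plan.n_events):
            date = period.start + dt.timedelta(days=int(offsets[k]))
            side_a, side_b = spec.actor_pool[rng.integers(len(spec.actor_pool))]
            rows.append(
                (f"E{eid:06d}", date.isoformat(), plan.department, int(sev[k]),
                 side_a, side_b, int(rng.integers(1, 5)))
            )
            eid += 1
        manifest_segments.append(
            dict(
                department=plan.department, period=plan.period,
                region=region_map.region_of(plan.department),
                n_events=plan.n_events, n_body=n_body, n_tail=n_tail,
                alpha_true=plan.alpha_true, xmin_true=plan.xmin_true,
                body_fraction=plan.body_fraction,
            )
        )

    # planted filter violations, appended after the clean rows
    all_depts = region_map.departments
    periods_cycle = [p.label for p in DEFAULT_PERIODS]
    for v in range(spec.n_geo_violations):
        period = _period_bounds(periods_cycle[v % 3])
        side_a, side_b = spec.actor_pool[rng.integers(len(spec.actor_pool))]
        date = period.start + dt.timedelta(days=int(rng.integers(0, 300)))
        rows.append(
            (f"E{eid:06d}", date.isoformat(), all_depts[v % len(all_depts)],
             int(sample_discrete_pl(2.5, 1, 1, rng)[0]), side_a, side_b,
             int(rng.integers(5, 8)))
        )
        eid += 1
    for v in range(spec.n_zero_fatalities):
        period = _period_bounds(periods_cycle[v % 3])
        side_a, side_b = spec.actor_pool[rng.integers(len(spec.actor_pool))]
        date = period.start + dt.timedelta(days=int(rng.integers(0, 300)))
        rows.append(
            (f"E{eid:06d}", date.isoformat(), all_depts[v % len(all_depts)],
             0, side_a, side_b, int(rng.integers(1, 5)))
        )
        eid += 1

    table = pd.DataFrame(
        rows,
        columns=["id", "date_start", "adm_1", "best", "side_a", "side_b", "where_prec"],
    )
    manifest = dict(
        seed=spec.seed,
        n_rows=len(rows),
        n_clean=sum(p.n_events for p in spec.segments),
        n_geo_violations=spec.n_geo_violations,
        n_zero_fatalities=spec.n_zero_fatalities,
        actors=sorted({a for pair in spec.actor_pool for a in pair}),
        segments=manifest_segments,
    )
    return table, manifest


# Per-period (department -> event count) geometry for the Colombia-scale
# fixture: region-period totals typical of a three-decade national
# conflict (period sums 776 / 2221 / 306, grand total 3303 kept events), spread
# over one or two departments per region.  alpha spans 2.0-3.5 with
# period-to-period movement; xmin 1-4 with a body where xmin > 1.
_COLOMBIA_PLAN: list[tuple[str, str, int, float, int, float]] = [
    # department, period, n_events, alpha_true, xmin_true, body_fraction
    ("Bolívar", "P1", 60, 2.2, 1, 0.0),
    ("Cesar", "P1", 31, 2.4, 2, 0.3),
    ("Antioquia", "P1", 147, 3.0, 3, 0.5),
    ("Chocó", "P1", 30, 2.2, 1, 0.0),
    ("Santander", "P1", 52, 2.5, 2, 0.35),
    ("Arauca", "P1", 46, 2.3, 1, 0.0),
    ("Cauca", "P1", 29, 3.5, 1, 0.0),
    ("Nariño", "P1", 49, 2.5, 2, 0.3),
    ("Tolima", "P1", 96, 2.8, 2, 0.4),
    ("Huila", "P1", 48, 3.2, 1, 0.0),
    ("Caquetá", "P1", 49, 2.5, 1, 0.0),
    ("Meta", "P1", 86, 2.0, 2, 0.3),
    ("Casanare", "P1", 53, 2.2, 1, 0.0),
    ("Bolívar", "P2", 180, 2.2, 1, 0.0),
    ("Cesar", "P2", 148, 2.1, 2, 0.35),
    ("Antioquia", "P2", 379, 2.2, 3, 0.55),
    ("Chocó", "P2", 74, 2.3, 1, 0.0),
    ("Santander", "P2", 108, 2.3, 2, 0.4),
    ("Arauca", "P2", 71, 2.1, 1, 0.0),
    ("Cauca", "P2", 133, 2.5, 2, 0.4),
    ("Nariño", "P2", 268, 2.4, 2, 0.45),
    ("Tolima", "P2", 225, 2.5, 2, 0.4),
    ("Huila", "P2", 140, 2.6, 1, 0.0),
    ("Caquetá", "P2", 224, 2.6, 2, 0.45),
    ("Meta", "P2", 181, 2.8, 2, 0.35),
    ("Casanare", "P2", 90, 3.3, 1, 0.0),
    ("Bolívar", "P3", 10, 2.4, 1, 0.0),
    ("Antioquia", "P3", 38, 1.8, 1, 0.0),
    ("Chocó", "P3", 15, 3.6, 1, 0.0),
    ("Santander", "P3", 28, 3.2, 1, 0.0),
    ("Cauca", "P3", 51, 2.5, 1, 0.0),
    ("Nariño", "P3", 34, 3.8, 1, 0.0),
    ("Tolima", "P3", 16, 2.0, 1, 0.0),
    ("Huila", "P3", 12, 1.9, 1, 0.0),
    ("Caquetá", "P3", 29, 5.3, 1, 0.0),
    ("Meta", "P3", 45, 3.2, 2, 0.3),
    ("Casanare", "P3", 28, 2.4, 1, 0.0),
]

#: planted low-precision rows in the Colombia-scale fixture (raw total 3517)
COLOMBIA_GEO_VIOLATIONS = 214


def colombia_spec(seed: int = 0) -> SyntheticSpec:
    segments = [
        SegmentPlan(
            department=d, period=p, n_events=n,
            alpha_true=a, xmin_true=x, body_fraction=b,
        )
        for d, p, n, a, x, b in _COLOMBIA_PLAN
    ]
    return SyntheticSpec(
        segments=segments,
        n_geo_violations=COLOMBIA_GEO_VIOLATIONS,
        seed=seed,
    )


def make_colombia_fixture(seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """The canned Colombia-scale fixture.

    3303 clean events across 37 (department, period) segments in all 7
    regions, plus 214 planted low-geo-precision rows (raw total 3517);
    true exponents span 1.8-5.3 with tails of about ten to several
    hundred events.
    """
    return generate_event_table(colombia_spec(seed))


def write_fixture(table: pd.DataFrame, manifest: dict, csv_path, manifest_path) -> None:
    table.to_csv(csv_path, index=False)
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
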