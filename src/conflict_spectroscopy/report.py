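"""Pipeline orchestration: from raw event CSV to analysis-ready result tables.

``run_full_analysis`` reads and filters the event table, segments it,
fits the power law per segment, attaches bootstrap P-values, runs the
subsampling null for sub-national segments, and writes:

* ``fits.csv``       — one row per segment (fit + GOF columns)
* ``subsampling.csv``— the null-comparison table per segment
* ``draws.csv``      — long-format valid draw exponents (boxplot data)
* ``ccdf/*.csv``     — empirical CCDF per segment for log-log plotting
* ``audit.json``     — filter counts, unmapped departments, degenerate fits
* ``manifest.json``  — config echo, seed, library versions

All randomness flows from the single top-level seed: each segment's RNG
substream is seeded by a stable hash of (seed, scope, unit, period), so
adding segments never perturbs the results of others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gof import DEFAULT_N_BOOT, GofResult, bootstrap_pvalue
from .io_ged import FilterConfig, read_events, filter_events
from .powerlaw import InsufficientDataError, PowerLawFit, select_xmin
from .segmentation import (
    ALL_PERIOD,
    DEFAULT_PERIODS,
    RegionMap,
    SegmentKey,
    SegmentedData,
    segment_events,
)
from .subsampling import DEFAULT_N_DRAWS, subsample_analysis, summaries_to_frame


def derive_seed(top_seed: int, *parts: str) -> int:
    """Stable per-segment substream seed (< 2**31), independent of other
    segments."""
    h = hashlib.sha256(("|".join([str(top_seed), *parts])).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    schema: dict | None = None
    filter_config: FilterConfig | None = None
    region_map_path: str | None = None
    periods: tuple = DEFAULT_PERIODS
    n_boot: int = DEFAULT_N_BOOT
    n_draws: int = DEFAULT_N_DRAWS
    subsample_n_boot: int = 1000
    seed: int = 0
    scopes: tuple = ("country", "region", "department")
    run_subsampling: bool = True


@dataclass
class ResultBundle:
    fits: pd.DataFrame
    subsampling: pd.DataFrame | None
    audit: dict
    manifest: dict
    output_dir: Path


def _fit_one(
    severities: np.ndarray, n_boot: int, seed: int
) -> tuple[PowerLawFit | None, GofResult | None]:
    try:
        fit = select_xmin(severities)
    except InsufficientDataError:
        return None, None
    gof = bootstrap_pvalue(severities, fit, n_boot=n_boot, seed=seed)
    return fit, gof


def run_full_analysis(cfg: RunConfig) -> ResultBundle:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "ccdf").mkdir(exist_ok=True)

    result = read_events(cfg.input_path, cfg.schema)
    fcfg = cfg.filter_config or FilterConfig(
        actor_whitelist=frozenset(
            {a for ev in result.events for a in (ev.side_a, ev.side_b)}
        )
    )
    kept, audit = filter_events(result.events, fcfg)
    region_map = (
        RegionMap.from_yaml(cfg.region_map_path)
        if cfg.region_map_path
        else RegionMap.default()
    )
    segmented = segment_events(kept, region_map, cfg.periods)

    fit_rows = []
    fits_by_key: dict[SegmentKey, tuple[PowerLawFit, GofResult]] = {}
    degenerate = []
    for key in sorted(segmented.segments):
        if key.scope not in cfg.scopes:
            continue
        sev = segmented.segments[key]
        seed = derive_seed(cfg.seed, "fit", key.scope, key.unit, key.period)
        fit, gof = _fit_one(sev, cfg.n_boot, seed)
        if fit is None:
            continue
        fits_by_key[key] = (fit, gof)
        if fit.degenerate:
            degenerate.append(list(key))
        fit_rows.append(
            dict(
                scope=key.scope, unit=key.unit, period=key.period,
                n_total=fit.n_total, n_tail=fit.n_tail, xmin=fit.xmin,
                alpha=fit.alpha, ks_stat=fit.ks_stat, p_value=gof.p_value,
            )
        )
        # empirical CCDF export for log-log plots
        vals, counts = np.unique(sev, return_counts=True)
        ccdf = 1.0 - np.concatenate([[0.0], np.cumsum(counts)[:-1]]) / sev.size
        pd.DataFrame({"x": vals, "ccdf": ccdf}).to_csv(
            out / "ccdf" / f"{key.scope}_{key.unit}_{key.period}.csv".replace("/", "-"),
            index=False, float_format="%.6g",
        )
    fits = pd.DataFrame(fit_rows)

    sub_frame = None
    draw_rows = []
    if cfg.run_subsampling:
        sub_rows = []
        for key, (fit, gof) in fits_by_key.items():
            if key.scope == "country" or key.period == ALL_PERIOD:
                continue
            pool_key = SegmentKey("country", "ALL", key.period)
            pooled = segmented.segments.get(pool_key)
            if pooled is None or pooled.size < fit.n_total:
                continue
            seed = derive_seed(cfg.seed, "sub", key.scope, key.unit, key.period)
            summary, valid = subsample_analysis(
                pooled, fit.n_total, fit, gof,
                period=key.period, n_draws=cfg.n_draws,
                n_boot=cfg.subsample_n_boot, seed=seed,
            )
            sub_rows.append((key.period, f"{key.scope}:{key.unit}", summary))
            draw_rows.extend(
                dict(period=key.period, unit=f"{key.scope}:{key.unit}", alpha=a)
                for a in valid
            )
        sub_frame = summaries_to_frame(sub_rows)

    # write outputs with fixed 6-significant-digit numerics
    fits.to_csv(out / "fits.csv", index=False, float_format="%.6g")
    if sub_frame is not None:
        sub_frame.to_csv(out / "subsampling.csv", index=False, float_format="%.6g")
        pd.DataFrame(draw_rows).to_csv(out / "draws.csv", index=False, float_format="%.6g")

    audit_doc = dict(
        filter=audit.__dict__,
        rejected_rows=[e.__dict__ for e in result.rejected],
        unmapped_departments=segmented.unmapped_departments,
        degenerate_fits=degenerate,
    )
    with open(out / "audit.json", "w", encoding="utf-8") as fh:
        json.dump(audit_doc, fh, indent=2)
    manifest = dict(
        version=__version__,
        seed=cfg.seed,
        input=str(cfg.input_path),
        n_boot=cfg.n_boot,
        n_draws=cfg.n_draws,
        subsample_n_boot=cfg.subsample_n_boot,
        scopes=list(cfg.scopes),
        numpy=np.__version__,
        pandas=pd.__version__,
        conventions=dict(
            percentile="linear interpolation (inclusive)",
            sd="sample (n-1)",
            subsample_replacement=False,
        ),
    )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)

    return ResultBundle(
        fits=fits, subsampling=sub_frame, audit=audit_doc, manifest=manifest,
        output_dir=out,
    )
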